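"""Recovery of fallow-site carbon relative to old-growth controls.

The recovery statistic is ``R = 100 · X_fallow / mean(X_control)`` — a
fallow site's carbon pool as a percentage of the mean of the same pool
over the old-growth replicate sites. R may exceed 100 (e.g. coarse
dead wood immediately after clearing). For the mixed-model responses,
undergrowth and litter are combined into ULBC before the ratio; the
pools tracked are LWBC, OLBC, CDWBC, ULBC and AGTBC.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .carbon import CarbonPools, pools_frame
from .inventory import FALLOW_CATEGORIES

__all__ = [
    "RECOVERY_POOLS",
    "COVARIATE_MAP",
    "recovery_pct",
    "control_means",
    "recovery_table",
    "recovery_summary",
    "recovery_from_category_means",
    "lmm_frame",
]

RECOVERY_POOLS = ("LWBC", "OLBC", "CDWBC", "ULBC", "AGTBC")

#: LMEM covariate abbreviation -> site-table column.
COVARIATE_MAP = {
    "FA": "fallow_age_yr",
    "DIS": "distance_m",
    "SL": "slope_deg",
    "PS": "patch_size_ha",
    "SOC": "soc_pct",
}


def recovery_pct(x_fallow: float, control_mean: float) -> float:
    """``100 · x_fallow / control_mean``; requires a positive control mean."""
    if not (control_mean > 0):
        raise ValueError("control mean must be > 0 for recovery to be defined")
    return 100.0 * x_fallow / control_mean


def _pool_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["ULBC"] = out["ubc"] + out["lbc"]
    for pool in ("lwbc", "olbc", "cdwbc", "agtbc"):
        out[pool.upper()] = out[pool]
    return out


def control_means(pools: list[CarbonPools], sites: pd.DataFrame) -> pd.Series:
    """Mean of each recovery pool over the old-growth replicate sites."""
    df = _pool_columns(pools_frame(pools, sites))
    og = df.loc[df["category"] == "OG"]
    if not len(og):
        raise ValueError("no old-growth control sites in the inventory")
    return og[list(RECOVERY_POOLS)].mean()


def recovery_table(pools: list[CarbonPools], sites: pd.DataFrame) -> pd.DataFrame:
    """Site-level recovery percentages for every fallow site × pool.

    Tidy columns: site_id, category, pool, recovery_pct. Defined only
    for non-old-growth sites.
    """
    ctrl = control_means(pools, sites)
    df = _pool_columns(pools_frame(pools, sites))
    fallow = df.loc[df["category"] != "OG"]
    rows = []
    for _, r in fallow.iterrows():
        for pool in RECOVERY_POOLS:
            rows.append({
                "site_id": r["site_id"],
                "category": r["category"],
                "pool": pool,
                "recovery_pct": recovery_pct(float(r[pool]), float(ctrl[pool])),
            })
    return pd.DataFrame(rows)


def recovery_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-category mean ± SD (and median) recovery per pool."""
    rows = []
    for (cat, pool), sub in table.groupby(["category", "pool"], sort=False):
        vals = sub["recovery_pct"].to_numpy(dtype=float)
        rows.append({
            "category": cat, "pool": pool,
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
            "median": float(np.median(vals)),
            "n": len(vals),
        })
    out = pd.DataFrame(rows)
    cat_order = {c: i for i, c in enumerate(FALLOW_CATEGORIES)}
    pool_order = {p: i for i, p in enumerate(RECOVERY_POOLS)}
    return out.sort_values(
        by=["category", "pool"],
        key=lambda s: s.map(cat_order if s.name == "category" else pool_order),
    ).reset_index(drop=True)


def lmm_frame(table: pd.DataFrame, sites: pd.DataFrame, pool: str) -> pd.DataFrame:
    """Mixed-model input frame for one pool's recovery.

    One row per fallow site with the response (``recovery_pct``), the
    five candidate covariates under their canonical abbreviations
    (FA, DIS, SL, PS, SOC) and the ``category`` grouping column.
    """
    sub = table.loc[table["pool"] == pool, ["site_id", "category", "recovery_pct"]]
    out = sub.merge(sites, on=["site_id", "category"] if "category" in sites
                    else "site_id", how="left")
    for abbr, col in COVARIATE_MAP.items():
        out[abbr] = out[col].astype(float)
    keep = ["site_id", "category", "recovery_pct", *COVARIATE_MAP]
    return out[keep]


def recovery_from_category_means(
    means: pd.DataFrame, pools: tuple[str, ...] = RECOVERY_POOLS
) -> pd.DataFrame:
    """Category-level recovery from a category × pool matrix of means.

    Used when only summary data exist (the published reference table):
    each fallow category's mean pool is expressed against the
    old-growth mean of the same pool. ``means`` must be indexed by
    category with one column per pool; a ULBC column is derived from
    UBC + LBC when absent.
    """
    m = means.copy()
    if "ULBC" not in m.columns and {"UBC", "LBC"} <= set(m.columns):
        m["ULBC"] = m["UBC"] + m["LBC"]
    if "OG" not in m.index:
        raise ValueError("category means must include the old-growth row 'OG'")
    rows = []
    for cat in m.index:
        if cat == "OG":
            continue
        for pool in pools:
            if pool not in m.columns:
                continue
            rows.append({
                "category": cat, "pool": pool,
                "recovery_pct": recovery_pct(
                    float(m.loc[cat, pool]), float(m.loc["OG", pool])
                ),
            })
    return pd.DataFrame(rows)
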