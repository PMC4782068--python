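"""Per-site, per-hectare aboveground carbon pools and their breakdowns.

Record-level dry masses from :mod:`.allometry` are multiplied by
component carbon fractions, summed per site, and scaled to Mg C ha⁻¹
on the slope-corrected (horizontal) sampled area. The five pools are

* LWBC — living woody biomass carbon (trees and palms ≥ 5 cm dbh),
* OLBC — other living biomass carbon (tree ferns and Abaca),
* CDWBC — coarse dead-wood biomass carbon,
* UBC / LBC — undergrowth and litter biomass carbon from the 1 m²
  quadrats,

and AGTBC is their sum. LWBC is additionally broken down by
successional guild, species origin and dbh/height size class; OLBC by
kind; CDWBC by stand form and decay class. Litter and undergrowth are
scaled on the quadrat area (n_transects × 1 m²), not the transect area,
with the same slope correction.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import agb_abaca, agb_tree, agb_tree_fern, cwd_dry_mass
from .config import AnalysisConfig, SizeClassEdges
from .inventory import CATEGORIES, DECAY_CLASSES, GUILDS, Inventory, ORIGINS, OTHER_KINDS, STAND_FORMS

__all__ = [
    "POOLS",
    "CarbonPools",
    "horizontal_area_ha",
    "site_pools",
    "all_site_pools",
    "pools_frame",
    "category_summary",
    "composition_percentages",
]

POOLS = ("lwbc", "olbc", "cdwbc", "ubc", "lbc")


@dataclass
class CarbonPools:
    """Carbon stocks (Mg C ha⁻¹) of one site, with breakdowns.

    ``breakdowns`` maps a family name (``guild``, ``origin``,
    ``dbh_class``, ``height_class``, ``olbc_kind``, ``stand_form``,
    ``decay_class``) to ``{level: Mg C ha⁻¹}``; each family sums to its
    parent pool.
    """

    site_id: str
    lwbc: float = 0.0
    olbc: float = 0.0
    cdwbc: float = 0.0
    ubc: float = 0.0
    lbc: float = 0.0
    breakdowns: dict = field(default_factory=dict)

    @property
    def agtbc(self) -> float:
        return self.lwbc + self.olbc + self.cdwbc + self.ubc + self.lbc

    @property
    def ulbc(self) -> float:
        """Undergrowth + litter combined (used as an LMEM response)."""
        return self.ubc + self.lbc

    def as_dict(self) -> dict:
        d = {p: getattr(self, p) for p in POOLS}
        d["agtbc"] = self.agtbc
        return d


def horizontal_area_ha(site) -> float:
    """Slope-corrected sampled ground area of a site in hectares.

    ``n_transects × length × width × cos(slope)`` / 10⁴. The default
    design (4 × 50 m × 5 m) on flat ground gives 0.1 ha.
    """
    slope = float(site["slope_deg"])
    if not (0 <= slope < 90):
        raise ValueError(f"slope_deg must be in [0, 90), got {slope}")
    area_m2 = (
        float(site["n_transects"])
        * float(site["transect_length_m"])
        * float(site["transect_width_m"])
    )
    return area_m2 * math.cos(math.radians(slope)) / 1e4


def _size_class(values: np.ndarray, edges: tuple[float, ...]) -> list[str]:
    labels = SizeClassEdges.labels(edges)
    idx = np.searchsorted(np.asarray(edges[1:]), values, side="right")
    return [labels[i] for i in idx]


def _group_sum(keys, carbon: np.ndarray, levels) -> dict[str, float]:
    out = {lvl: 0.0 for lvl in levels}
    if len(carbon):
        s = pd.Series(carbon).groupby(list(keys)).sum()
        for lvl, v in s.items():
            out[lvl] = out.get(lvl, 0.0) + float(v)
    return out


def site_pools(
    inventory: Inventory,
    site_id: str,
    config: AnalysisConfig | None = None,
) -> CarbonPools:
    """Compute all carbon pools and breakdowns for one site.

    A component with no records contributes 0 (not an error). Live
    stems with no recorded wood density fall back to the configured
    global default.
    """
    cfg = config or AnalysisConfig()
    fr, dens, coef = cfg.carbon_fractions, cfg.decay_densities, cfg.coefficients
    site = inventory.site(site_id)
    area_ha = horizontal_area_ha(site)
    cos_slope = math.cos(math.radians(float(site["slope_deg"])))
    pools = CarbonPools(site_id=site_id)
    bd = pools.breakdowns

    # living woody ----------------------------------------------------
    stems = inventory.live_stems.loc[inventory.live_stems["site_id"] == site_id]
    if len(stems):
        dbh = stems["dbh_cm"].to_numpy(dtype=float)
        h = stems["height_m"].to_numpy(dtype=float)
        rho = stems["wood_density_g_cm3"].to_numpy(dtype=float)
        rho = np.where(np.isfinite(rho), rho, cfg.default_wood_density_g_cm3)
        carbon = agb_tree(dbh, h, rho, coef) * fr.tree / 1000.0 / area_ha  # Mg C/ha
        pools.lwbc = float(np.sum(carbon))
        bd["guild"] = _group_sum(stems["guild"], carbon, GUILDS)
        bd["origin"] = _group_sum(stems["origin"], carbon, ORIGINS)
        bd["dbh_class"] = _group_sum(
            _size_class(dbh, cfg.size_classes.dbh_cm), carbon,
            SizeClassEdges.labels(cfg.size_classes.dbh_cm))
        bd["height_class"] = _group_sum(
            _size_class(h, cfg.size_classes.height_m), carbon,
            SizeClassEdges.labels(cfg.size_classes.height_m))
    else:
        bd["guild"] = {g: 0.0 for g in GUILDS}
        bd["origin"] = {o: 0.0 for o in ORIGINS}
        bd["dbh_class"] = {l: 0.0 for l in SizeClassEdges.labels(cfg.size_classes.dbh_cm)}
        bd["height_class"] = {l: 0.0 for l in SizeClassEdges.labels(cfg.size_classes.height_m)}

    # other living ----------------------------------------------------
    other = inventory.other_living.loc[inventory.other_living["site_id"] == site_id]
    olbc_kind = {k: 0.0 for k in OTHER_KINDS}
    for kind, model, frac in (
        ("tree_fern", agb_tree_fern, fr.fern),
        ("abaca", agb_abaca, fr.abaca),
    ):
        rows = other.loc[other["kind"] == kind]
        if len(rows):
            mass_kg = np.sum(model(rows["dbh_cm"].to_numpy(dtype=float), coef))
            olbc_kind[kind] = float(mass_kg) * frac / 1000.0 / area_ha
    bd["olbc_kind"] = olbc_kind
    pools.olbc = sum(olbc_kind.values())

    # coarse dead wood ------------------------------------------------
    cwd = inventory.dead_wood.loc[inventory.dead_wood["site_id"] == site_id]
    if len(cwd):
        mass = np.array([
            cwd_dry_mass(d, l, dc, dens) * fr.cwd(dc)
            for d, l, dc in zip(
                cwd["diameter_cm"].astype(float),
                cwd["length_in_transect_m"].astype(float),
                cwd["decay_class"],
            )
        ]) / 1000.0 / area_ha
        pools.cdwbc = float(np.sum(mass))
        bd["stand_form"] = _group_sum(cwd["stand_form"], mass, STAND_FORMS)
        bd["decay_class"] = _group_sum(cwd["decay_class"], mass, DECAY_CLASSES)
    else:
        bd["stand_form"] = {s: 0.0 for s in STAND_FORMS}
        bd["decay_class"] = {d: 0.0 for d in DECAY_CLASSES}

    # quadrats: litter & undergrowth ----------------------------------
    quad = inventory.quadrats.loc[inventory.quadrats["site_id"] == site_id]
    for component, attr, default_frac in (
        ("litter", "lbc", fr.litter),
        ("undergrowth", "ubc", fr.undergrowth),
    ):
        rows = quad.loc[quad["component"] == component]
        if not len(rows):
            continue
        mass_g = rows["dry_mass_g"].to_numpy(dtype=float)
        frac = rows["carbon_fraction"].to_numpy(dtype=float)
        frac = np.where(np.isfinite(frac), frac, default_frac)
        carbon_mg = float(np.sum(mass_g * frac)) * 1e-6  # g -> Mg
        quad_area_ha = len(rows) * 1.0 * cos_slope / 1e4  # 1 m² quadrats
        setattr(pools, attr, carbon_mg / quad_area_ha)

    return pools


def all_site_pools(
    inventory: Inventory, config: AnalysisConfig | None = None
) -> list[CarbonPools]:
    return [
        site_pools(inventory, sid, config) for sid in inventory.sites["site_id"]
    ]


def pools_frame(pools: list[CarbonPools], sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide per-site frame of pool totals; merges ``category`` when the
    site table is given."""
    df = pd.DataFrame([{"site_id": p.site_id, **p.as_dict()} for p in pools])
    if sites is not None:
        df = df.merge(sites[["site_id", "category"]], on="site_id", how="left")
    return df


def _flatten(p: CarbonPools) -> dict[str, float]:
    out = p.as_dict()
    parent = {
        "guild": "lwbc", "origin": "lwbc", "dbh_class": "lwbc",
        "height_class": "lwbc", "olbc_kind": "olbc",
        "stand_form": "cdwbc", "decay_class": "cdwbc",
    }
    for family, cells in p.breakdowns.items():
        for level, v in cells.items():
            out[f"{parent[family]}.{family}.{level}"] = v
    return out


def category_summary(pools: list[CarbonPools], sites: pd.DataFrame) -> pd.DataFrame:
    """Per-category mean and standard error (sd/√n over replicate
    sites) for every pool and breakdown cell.

    Tidy output: category, metric, mean, se, n. A category with a
    single site reports SE as NaN; one with no sites is skipped with a
    warning.
    """
    flat = pd.DataFrame([{"site_id": p.site_id, **_flatten(p)} for p in pools])
    flat = flat.merge(sites[["site_id", "category"]], on="site_id", how="left")
    rows = []
    for cat in CATEGORIES:
        sub = flat.loc[flat["category"] == cat]
        if not len(sub):
            warnings.warn(f"category {cat} has no sites; excluded from summary")
            continue
        n = len(sub)
        for metric in flat.columns.drop(["site_id", "category"]):
            vals = sub[metric].to_numpy(dtype=float)
            se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
            rows.append({
                "category": cat, "metric": metric,
                "mean": float(np.mean(vals)), "se": se, "n": n,
            })
    return pd.DataFrame(rows)


def composition_percentages(pools: CarbonPools) -> dict[str, dict[str, float]]:
    """Percentage contributions within each composition family.

    Families: each pool as % of AGTBC; guild, origin, dbh and height
    classes as % of LWBC; kind as % of OLBC; stand form and decay class
    as % of CDWBC. Each returned family sums to 100; a family whose
    denominator is zero is omitted.
    """
    out: dict[str, dict[str, float]] = {}
    if pools.agtbc > 0:
        out["pool"] = {
            p.upper(): 100.0 * getattr(pools, p) / pools.agtbc for p in POOLS
        }
    denom = {
        "guild": pools.lwbc, "origin": pools.lwbc, "dbh_class": pools.lwbc,
        "height_class": pools.lwbc, "olbc_kind": pools.olbc,
        "stand_form": pools.cdwbc, "decay_class": pools.cdwbc,
    }
    for family, cells in pools.breakdowns.items():
        d = denom.get(family, 0.0)
        if d > 0:
            out[family] = {lvl: 100.0 * v / d for lvl, v in cells.items()}
    return out
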