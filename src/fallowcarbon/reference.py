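"""Published category-mean carbon pools for a post-kaingin chronosequence.

The field study this package models (25 sites on Leyte Island, the
Philippines: four fallow-age categories plus old-growth control, five
replicates each) reported per-category mean ± SE aboveground biomass
carbon for every pool and breakdown. Those printed category means are
bundled here as a tidy table; they are the worked-example inputs for the
recovery and composition statistics, since the underlying site-level
data were never deposited.

Values are Mg C ha⁻¹. A zero-variance cell printed without an SE is
stored with SE 0.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["reference_means", "reference_pool_means"]

# (pool, breakdown level or None) -> per-category (mean, se) for
# SA0_5, SA6_10, SA11_20, SA21_30, OG in that order.
_ROWS = [
    ("LWBC", None, (33.42, 55.25), (74.18, 54.15), (111.81, 74.65), (120.02, 52.05), (316.96, 130.63)),
    ("LWBC", "pioneer", (4.09, 5.31), (37.30, 43.85), (29.32, 20.78), (24.57, 6.54), (87.58, 45.63)),
    ("LWBC", "secondary", (6.75, 7.97), (20.13, 6.28), (33.65, 22.4), (45.03, 18.78), (74.31, 36.66)),
    ("LWBC", "climax", (22.57, 49.0), (16.75, 12.27), (48.85, 55.56), (50.42, 35.68), (155.07, 84.03)),
    ("LWBC", "native", (17.63, 23.35), (60.32, 42.23), (78.17, 52.47), (75.79, 33.68), (256.14, 108.27)),
    ("LWBC", "endemic", (15.43, 32.71), (14.50, 12.03), (33.24, 28.13), (41.66, 30.67), (60.83, 31.7)),
    ("LWBC", "exotic", (0.35, 0.79), (0.0, 0.0), (0.4, 0.61), (2.57, 5.14), (0.0, 0.0)),
    ("OLBC", None, (0.09, 0.17), (1.45, 1.34), (0.40, 0.27), (0.34, 0.37), (0.21, 0.30)),
    ("OLBC", "tree_fern", (0.08, 0.17), (1.41, 1.33), (0.32, 0.31), (0.23, 0.25), (0.21, 0.30)),
    ("OLBC", "abaca", (0.01, 0.02), (0.04, 0.05), (0.08, 0.06), (0.11, 0.14), (0.0, 0.0)),
    ("CDWBC", None, (126.65, 22.58), (25.26, 25.0), (9.95, 4.97), (11.87, 12.57), (3.91, 1.17)),
    ("CDWBC", "standing", (108.28, 19.46), (18.21, 24.74), (2.53, 1.07), (4.47, 5.74), (0.31, 0.25)),
    ("CDWBC", "downed", (18.37, 11.70), (7.05, 5.68), (7.42, 5.49), (7.40, 7.33), (3.60, 1.07)),
    ("CDWBC", "fresh", (115.29, 22.2), (2.06, 2.77), (0.27, 0.28), (1.13, 1.85), (0.0, 0.0)),
    ("CDWBC", "moderate", (7.85, 7.69), (17.20, 25.39), (4.69, 3.68), (6.72, 8.45), (0.3, 0.21)),
    ("CDWBC", "high", (3.04, 3.56), (5.93, 4.47), (4.97, 3.76), (4.0, 4.5), (3.57, 1.23)),
    ("CDWBC", "burnt", (0.47, 1.01), (0.08, 0.13), (0.02, 0.05), (0.01, 0.02), (0.04, 0.09)),
    ("UBC", None, (0.08, 0.06), (0.10, 0.03), (0.12, 0.04), (0.15, 0.08), (0.11, 0.04)),
    ("LBC", None, (0.07, 0.04), (0.09, 0.03), (0.13, 0.09), (0.17, 0.10), (0.10, 0.02)),
    ("AGTBC", None, (160.3, 55.86), (101.09, 55.98), (122.41, 74.95), (132.54, 57.07), (321.29, 130.96)),
]

_CATS = ("SA0_5", "SA6_10", "SA11_20", "SA21_30", "OG")


def reference_means() -> pd.DataFrame:
    """Tidy frame of the published category means.

    Columns: pool, level (breakdown level, NaN for the pool total),
    category, mean, se — all stocks in Mg C ha⁻¹.
    """
    records = []
    for pool, level, *cells in _ROWS:
        for cat, (mean, se) in zip(_CATS, cells):
            records.append(
                {"pool": pool, "level": level, "category": cat,
                 "mean": mean, "se": se}
            )
    return pd.DataFrame(records)


def reference_pool_means() -> pd.DataFrame:
    """Wide category × pool matrix of the published pool-total means."""
    df = reference_means()
    totals = df.loc[df["level"].isna()]
    return totals.pivot(index="category", columns="pool", values="mean").loc[list(_CATS)]
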