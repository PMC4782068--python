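"""Seeded synthetic forest-inventory generator.

Emulates the study design the package analyses: 25 sites — four
fallow-age categories (SA0–5, SA6–10, SA11–20, SA21–30) plus an
old-growth control, five replicate sites each — sampled with four
50 m × 5 m transects per site and one 1 m² quadrat per transect. The
per-category biomass structure (stem density, dbh/height distributions,
guild/origin mixtures, dead-wood load and decay mix, quadrat masses) is
calibrated so that the per-hectare carbon pools land on the magnitudes
reported for the Leyte Island chronosequence: e.g. old-growth living
woody carbon ≈ 317 Mg C ha⁻¹ and new-fallow coarse-dead-wood carbon
≈ 127 Mg C ha⁻¹. Distribution families (truncated-Weibull dbh,
power-law height with lognormal scatter) are generator choices that
need only reproduce pool magnitudes, not stand structure.

Site covariates carry built-in collinearity — elevation tracks slope
and leaf area index tracks fallow age — so the collinearity screen has
something real to find.

Everything is driven by one integer seed: the same seed yields a
byte-identical inventory.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .carbon import site_pools
from .config import AnalysisConfig
from .inventory import CATEGORIES, Inventory
from .stats import CANDIDATE_VARS

__all__ = [
    "CategoryParams",
    "GeneratorConfig",
    "generate_inventory",
    "generate_recovery_scenario",
    "SPECIES_POOL",
]

#: (species, genus, base wood density g cm⁻³, sampling weight).
#: Parashorea malaanonan carries an elevated abundance weight so it
#: ranks first in living-woody-carbon contribution on default seeds.
SPECIES_POOL = [
    ("Parashorea malaanonan", "Parashorea", 0.45, 0.30),
    ("Lithocarpus llanosii", "Lithocarpus", 0.62, 0.10),
    ("Ficus balete", "Ficus", 0.39, 0.09),
    ("Shorea contorta", "Shorea", 0.44, 0.08),
    ("Calophyllum blancoi", "Calophyllum", 0.53, 0.08),
    ("Petersianthus quadrialatus", "Petersianthus", 0.58, 0.07),
    ("Bischofia javanica", "Bischofia", 0.62, 0.07),
    ("Macaranga bicolor", "Macaranga", 0.36, 0.08),
    ("Melanolepis multiglandulosa", "Melanolepis", 0.33, 0.07),
    ("Artocarpus blancoi", "Artocarpus", 0.47, 0.06),
]


@dataclass(frozen=True)
class CategoryParams:
    """Stand-structure parameters of one fallow category."""

    stems_per_site: float          # Poisson mean, per 0.1 ha site
    dbh_weibull_shape: float
    dbh_weibull_scale: float       # cm; truncated below at 5 cm
    height_a: float                # H = a · D^b · lognormal(0, sigma)
    height_b: float
    height_sigma: float
    density_sd: float              # scatter around the species base density
    guild_probs: tuple[float, float, float]    # pioneer, secondary, climax
    origin_probs: tuple[float, float, float]   # native, endemic, exotic
    fern_per_site: float           # Poisson means
    abaca_per_site: float
    cwd_per_site: float
    cwd_diam_mu: float             # lognormal of diameter (cm)
    cwd_diam_sigma: float
    cwd_length_mu: float           # lognormal of in-transect length (m)
    cwd_length_sigma: float
    standing_prob: float
    decay_probs: tuple[float, float, float, float]  # fresh, moderate, high, burnt
    litter_mass_g: float           # lognormal median per 1 m² quadrat
    undergrowth_mass_g: float

    def __post_init__(self) -> None:
        for name in ("guild_probs", "origin_probs", "decay_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be non-negative and sum to 1")


_DEFAULT_CATEGORIES: dict[str, CategoryParams] = {
    "SA0_5": CategoryParams(
        stems_per_site=65, dbh_weibull_shape=1.6, dbh_weibull_scale=14.0,
        height_a=2.0, height_b=0.62, height_sigma=0.15, density_sd=0.04,
        guild_probs=(0.12, 0.20, 0.68), origin_probs=(0.53, 0.46, 0.01),
        fern_per_site=0.9, abaca_per_site=0.2,
        cwd_per_site=54, cwd_diam_mu=math.log(30), cwd_diam_sigma=0.35,
        cwd_length_mu=math.log(9), cwd_length_sigma=0.45,
        standing_prob=0.85, decay_probs=(0.910, 0.062, 0.024, 0.004),
        litter_mass_g=12.5, undergrowth_mass_g=14,
    ),
    "SA6_10": CategoryParams(
        stems_per_site=82, dbh_weibull_shape=1.5, dbh_weibull_scale=16.5,
        height_a=2.2, height_b=0.64, height_sigma=0.15, density_sd=0.04,
        guild_probs=(0.50, 0.27, 0.23), origin_probs=(0.81, 0.19, 0.0),
        fern_per_site=15.5, abaca_per_site=0.7,
        cwd_per_site=31, cwd_diam_mu=math.log(24), cwd_diam_sigma=0.35,
        cwd_length_mu=math.log(7), cwd_length_sigma=0.45,
        standing_prob=0.72, decay_probs=(0.082, 0.680, 0.235, 0.003),
        litter_mass_g=16, undergrowth_mass_g=18,
    ),
    "SA11_20": CategoryParams(
        stems_per_site=85, dbh_weibull_shape=1.4, dbh_weibull_scale=16.5,
        height_a=2.4, height_b=0.66, height_sigma=0.15, density_sd=0.04,
        guild_probs=(0.26, 0.30, 0.44), origin_probs=(0.70, 0.296, 0.004),
        fern_per_site=3.7, abaca_per_site=1.2,
        cwd_per_site=22, cwd_diam_mu=math.log(20), cwd_diam_sigma=0.35,
        cwd_length_mu=math.log(6), cwd_length_sigma=0.45,
        standing_prob=0.25, decay_probs=(0.027, 0.471, 0.500, 0.002),
        litter_mass_g=23.5, undergrowth_mass_g=21.5,
    ),
    "SA21_30": CategoryParams(
        stems_per_site=85, dbh_weibull_shape=1.3, dbh_weibull_scale=15.5,
        height_a=2.5, height_b=0.67, height_sigma=0.15, density_sd=0.04,
        guild_probs=(0.20, 0.38, 0.42), origin_probs=(0.63, 0.35, 0.02),
        fern_per_site=3.3, abaca_per_site=2.0,
        cwd_per_site=24, cwd_diam_mu=math.log(21), cwd_diam_sigma=0.35,
        cwd_length_mu=math.log(6), cwd_length_sigma=0.45,
        standing_prob=0.38, decay_probs=(0.095, 0.567, 0.337, 0.001),
        litter_mass_g=30, undergrowth_mass_g=26,
    ),
    "OG": CategoryParams(
        stems_per_site=110, dbh_weibull_shape=1.1, dbh_weibull_scale=16.0,
        height_a=2.8, height_b=0.70, height_sigma=0.15, density_sd=0.04,
        guild_probs=(0.28, 0.23, 0.49), origin_probs=(0.81, 0.19, 0.0),
        fern_per_site=2.5, abaca_per_site=0.0,
        cwd_per_site=16, cwd_diam_mu=math.log(18), cwd_diam_sigma=0.35,
        cwd_length_mu=math.log(5), cwd_length_sigma=0.45,
        standing_prob=0.08, decay_probs=(0.0, 0.077, 0.913, 0.010),
        litter_mass_g=18.5, undergrowth_mass_g=20.5,
    ),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of the synthetic study.

    ``categories`` maps each category code to its
    :class:`CategoryParams`; covariate fields define the site-level
    environment, including the built-in collinearity (elevation ~
    slope, LAI ~ fallow age).
    """

    seed: int = 0
    replicates: int = 5
    n_transects: int = 4
    transect_length_m: float = 50.0
    transect_width_m: float = 5.0
    categories: dict[str, CategoryParams] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORIES)
    )
    # covariate distributions
    slope_range_deg: tuple[float, float] = (5.0, 35.0)
    patch_lognorm: tuple[float, float] = (math.log(4.0), 0.7)  # ha
    patch_min_ha: float = 1.0
    distance_range_m: tuple[float, float] = (100.0, 3000.0)
    soc_range_pct: tuple[float, float] = (2.5, 8.0)
    elevation_base_m: float = 150.0
    elevation_per_slope: float = 9.0   # drives elevation–slope collinearity
    elevation_noise_m: float = 35.0
    lai_base: float = 1.2
    lai_per_year: float = 0.13         # drives LAI–fallow-age collinearity
    lai_noise: float = 0.35
    lai_og: tuple[float, float] = (5.5, 0.4)
    carbon_fraction_quadrat: tuple[float, float] = (0.48, 0.02)

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.categories]
        if missing:
            raise ValueError(f"GeneratorConfig missing categories {missing}")


_AGE_RANGES = {
    "SA0_5": (1.0, 5.0), "SA6_10": (6.0, 10.0),
    "SA11_20": (11.0, 20.0), "SA21_30": (21.0, 30.0),
}

_SP_NAMES = [s[0] for s in SPECIES_POOL]
_SP_GENUS = {s[0]: s[1] for s in SPECIES_POOL}
_SP_RHO = {s[0]: s[2] for s in SPECIES_POOL}
_SP_W = np.array([s[3] for s in SPECIES_POOL])
_SP_W = _SP_W / _SP_W.sum()


def _truncated_weibull(rng, shape: float, scale: float, size: int,
                       lower: float = 5.0) -> np.ndarray:
    # inverse-CDF sampling of a Weibull conditioned on X >= lower
    e = rng.exponential(size=size)
    return scale * ((lower / scale) ** shape + e) ** (1.0 / shape)


def _make_sites(rng, config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for cat in CATEGORIES:
        for rep in range(1, config.replicates + 1):
            slope = rng.uniform(*config.slope_range_deg)
            if cat == "OG":
                age = np.nan
                lai = max(0.1, rng.normal(*config.lai_og))
            else:
                age = rng.uniform(*_AGE_RANGES[cat])
                lai = max(
                    0.1,
                    config.lai_base + config.lai_per_year * age
                    + rng.normal(0, config.lai_noise),
                )
            rows.append({
                "site_id": f"{cat}-r{rep}",
                "category": cat,
                "fallow_age_yr": age,
                "slope_deg": slope,
                "patch_size_ha": max(
                    config.patch_min_ha, rng.lognormal(*config.patch_lognorm)
                ),
                "distance_m": rng.uniform(*config.distance_range_m),
                "soc_pct": rng.uniform(*config.soc_range_pct),
                "elevation_m": (
                    config.elevation_base_m
                    + config.elevation_per_slope * slope
                    + rng.normal(0, config.elevation_noise_m)
                ),
                "lai": lai,
                "n_transects": config.n_transects,
                "transect_length_m": config.transect_length_m,
                "transect_width_m": config.transect_width_m,
            })
    return pd.DataFrame(rows)


def _draw_stems(rng, site_id: str, params: CategoryParams, n: int,
                n_transects: int) -> list[dict]:
    if n <= 0:
        return []
    dbh = _truncated_weibull(rng, params.dbh_weibull_shape,
                             params.dbh_weibull_scale, n)
    height = (params.height_a * dbh ** params.height_b
              * rng.lognormal(0.0, params.height_sigma, size=n))
    sp_idx = rng.choice(len(_SP_NAMES), size=n, p=_SP_W)
    guild = rng.choice(["pioneer", "secondary", "climax"], size=n,
                       p=params.guild_probs)
    origin = rng.choice(["native", "endemic", "exotic"], size=n,
                        p=params.origin_probs)
    transect = rng.integers(1, n_transects + 1, size=n)
    rows = []
    for i in range(n):
        sp = _SP_NAMES[sp_idx[i]]
        rho = float(np.clip(
            _SP_RHO[sp] + rng.normal(0, params.density_sd), 0.15, 1.2))
        rows.append({
            "site_id": site_id, "transect_id": f"T{transect[i]}",
            "species_name": sp, "genus": _SP_GENUS[sp],
            "dbh_cm": float(dbh[i]), "height_m": float(height[i]),
            "wood_density_g_cm3": rho,
            "guild": str(guild[i]), "origin": str(origin[i]),
        })
    return rows


def _draw_other(rng, site_id, params, n_transects) -> list[dict]:
    rows = []
    for kind, mean in (("tree_fern", params.fern_per_site),
                       ("abaca", params.abaca_per_site)):
        n = int(rng.poisson(mean))
        for _ in range(n):
            rows.append({
                "site_id": site_id,
                "transect_id": f"T{int(rng.integers(1, n_transects + 1))}",
                "kind": kind,
                "dbh_cm": float(5.0 + rng.gamma(2.0, 3.0)),
            })
    return rows


def _draw_cwd(rng, site_id, params, n_transects) -> list[dict]:
    n = int(rng.poisson(params.cwd_per_site))
    rows = []
    classes = ["fresh", "moderate", "high", "burnt"]
    for _ in range(n):
        rows.append({
            "site_id": site_id,
            "transect_id": f"T{int(rng.integers(1, n_transects + 1))}",
            "diameter_cm": float(max(
                5.0, rng.lognormal(params.cwd_diam_mu, params.cwd_diam_sigma))),
            "length_in_transect_m": float(max(
                0.3, rng.lognormal(params.cwd_length_mu, params.cwd_length_sigma))),
            "stand_form": "standing" if rng.random() < params.standing_prob
                          else "downed",
            "decay_class": str(rng.choice(classes, p=params.decay_probs)),
        })
    return rows


def _draw_quadrats(rng, site_id, params, n_transects, cf) -> list[dict]:
    rows = []
    for t in range(1, n_transects + 1):
        for component, median in (("litter", params.litter_mass_g),
                                  ("undergrowth", params.undergrowth_mass_g)):
            rows.append({
                "site_id": site_id, "transect_id": f"T{t}",
                "component": component,
                "dry_mass_g": float(rng.lognormal(math.log(median), 0.4)),
                "carbon_fraction": float(np.clip(
                    rng.normal(*cf), 0.35, 0.60)),
            })
    return rows


def generate_inventory(config: GeneratorConfig | None = None) -> Inventory:
    """Generate a complete validated inventory for the 25-site design.

    Deterministic under ``config.seed``: the same configuration yields
    an identical inventory (and identical CSV bytes when written).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    sites = _make_sites(rng, config)
    stems, other, cwd, quads = [], [], [], []
    for _, site in sites.iterrows():
        params = config.categories[site["category"]]
        n = int(rng.poisson(params.stems_per_site))
        stems += _draw_stems(rng, site["site_id"], params, n, config.n_transects)
        other += _draw_other(rng, site["site_id"], params, config.n_transects)
        cwd += _draw_cwd(rng, site["site_id"], params, config.n_transects)
        quads += _draw_quadrats(rng, site["site_id"], params,
                                config.n_transects,
                                config.carbon_fraction_quadrat)
    from .inventory import (DEAD_WOOD_COLUMNS, LIVE_STEM_COLUMNS,
                            OTHER_LIVING_COLUMNS, QUADRAT_COLUMNS)
    inv = Inventory(
        sites=sites,
        live_stems=pd.DataFrame(stems, columns=LIVE_STEM_COLUMNS),
        other_living=pd.DataFrame(other, columns=OTHER_LIVING_COLUMNS),
        dead_wood=pd.DataFrame(cwd, columns=DEAD_WOOD_COLUMNS),
        quadrats=pd.DataFrame(quads, columns=QUADRAT_COLUMNS),
    )
    return inv.validate()


def generate_recovery_scenario(
    config: GeneratorConfig | None = None,
    *,
    effects: dict[str, float] | None = None,
    intercept: float = 30.0,
    noise_sd: float = 3.0,
    analysis_config: AnalysisConfig | None = None,
) -> tuple[Inventory, dict]:
    """Generate an inventory whose living-woody recovery follows a known
    linear model in chosen site covariates.

    Old-growth sites are generated as usual and define the control
    mean; each fallow site's living woody biomass is then constructed
    so its recovery percentage equals
    ``intercept + Σ β_v · z(v) + N(0, noise_sd)`` (z-scores over the 20
    fallow sites), by drawing stems until the target stock is reached
    and solving the last stem's height to hit it exactly. Returns the
    inventory together with a ground-truth record (betas, noise,
    control mean, per-site target recoveries).

    ``effects`` maps covariate names (subset of FA, DIS, SL, PS, SOC)
    to slopes in recovery-percentage units per covariate SD.
    """
    config = config or GeneratorConfig()
    effects = dict(effects or {})
    bad = sorted(set(effects) - set(CANDIDATE_VARS))
    if bad:
        raise ValueError(f"effects on unknown/excluded covariates: {bad}")
    acfg = analysis_config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)

    sites = _make_sites(rng, config)
    stems, other, cwd, quads = [], [], [], []

    # old-growth first: defines the control mean
    for _, site in sites.loc[sites["category"] == "OG"].iterrows():
        params = config.categories["OG"]
        n = int(rng.poisson(params.stems_per_site))
        stems += _draw_stems(rng, site["site_id"], params, n, config.n_transects)
        other += _draw_other(rng, site["site_id"], params, config.n_transects)
        cwd += _draw_cwd(rng, site["site_id"], params, config.n_transects)
        quads += _draw_quadrats(rng, site["site_id"], params,
                                config.n_transects,
                                config.carbon_fraction_quadrat)
    from .inventory import (DEAD_WOOD_COLUMNS, LIVE_STEM_COLUMNS,
                            OTHER_LIVING_COLUMNS, QUADRAT_COLUMNS)
    og_inv = Inventory(
        sites=sites.loc[sites["category"] == "OG"].reset_index(drop=True),
        live_stems=pd.DataFrame(stems, columns=LIVE_STEM_COLUMNS),
        other_living=pd.DataFrame(other, columns=OTHER_LIVING_COLUMNS),
        dead_wood=pd.DataFrame(cwd, columns=DEAD_WOOD_COLUMNS),
        quadrats=pd.DataFrame(quads, columns=QUADRAT_COLUMNS),
    )
    control_mean = float(np.mean([
        site_pools(og_inv, sid, acfg).lwbc
        for sid in og_inv.sites["site_id"]
    ]))

    fallow = sites.loc[sites["category"] != "OG"]
    cov_map = {"FA": "fallow_age_yr", "DIS": "distance_m", "SL": "slope_deg",
               "PS": "patch_size_ha", "SOC": "soc_pct"}
    z = {}
    for var in effects:
        v = fallow[cov_map[var]].to_numpy(dtype=float)
        z[var] = (v - v.mean()) / v.std()
    noise = rng.normal(0.0, noise_sd, size=len(fallow)) if noise_sd > 0 else \
        np.zeros(len(fallow))
    targets = {}
    coef = acfg.coefficients
    for j, (_, site) in enumerate(fallow.iterrows()):
        r = intercept + sum(b * z[v][j] for v, b in effects.items()) + noise[j]
        r = max(r, 1.0)
        targets[site["site_id"]] = r
        area_ha = (config.n_transects * config.transect_length_m
                   * config.transect_width_m
                   * math.cos(math.radians(site["slope_deg"])) / 1e4)
        target_agb_kg = (r / 100.0 * control_mean) * area_ha * 1000.0 \
            / acfg.carbon_fractions.tree
        params = config.categories[site["category"]]
        cum = 0.0
        site_stems: list[dict] = []
        while cum < target_agb_kg:
            row = _draw_stems(rng, site["site_id"], params, 1,
                              config.n_transects)[0]
            agb = coef.tree_a * (row["wood_density_g_cm3"]
                                 * row["dbh_cm"] ** 2
                                 * row["height_m"]) ** coef.tree_b
            if cum + agb >= target_agb_kg:
                needed = target_agb_kg - cum
                row["height_m"] = float(
                    (needed / coef.tree_a) ** (1.0 / coef.tree_b)
                    / (row["wood_density_g_cm3"] * row["dbh_cm"] ** 2))
                agb = needed
            site_stems.append(row)
            cum += agb
        stems += site_stems
        other += _draw_other(rng, site["site_id"], params, config.n_transects)
        cwd += _draw_cwd(rng, site["site_id"], params, config.n_transects)
        quads += _draw_quadrats(rng, site["site_id"], params,
                                config.n_transects,
                                config.carbon_fraction_quadrat)

    inv = Inventory(
        sites=sites,
        live_stems=pd.DataFrame(stems, columns=LIVE_STEM_COLUMNS),
        other_living=pd.DataFrame(other, columns=OTHER_LIVING_COLUMNS),
        dead_wood=pd.DataFrame(cwd, columns=DEAD_WOOD_COLUMNS),
        quadrats=pd.DataFrame(quads, columns=QUADRAT_COLUMNS),
    ).validate()
    truth = {
        "effects": effects, "intercept": intercept, "noise_sd": noise_sd,
        "pool": "LWBC", "control_mean": control_mean,
        "target_recovery_pct": targets,
    }
    return inv, truth
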