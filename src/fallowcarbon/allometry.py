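"""Allometric biomass equations and dead-wood geometry.

Pure functions from field measurements to dry biomass. Unit conventions
are centralised here: diameters in cm, heights/lengths in m, wood
density in g cm⁻³; every function returns kilograms of dry matter except
:func:`cwd_volume` (m³). The tree-fern model natively predicts grams and
is converted before return.
"""
from __future__ import annotations

import math

import numpy as np

from .config import AllometryCoefficients, DecayDensityTable

__all__ = [
    "agb_tree",
    "agb_tree_fern",
    "agb_tree_fern_g",
    "agb_abaca",
    "cwd_volume",
    "cwd_dry_mass",
]

_DEFAULT = AllometryCoefficients()


def _check_positive(**values) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"{name} must be positive and finite")


def agb_tree(dbh_cm, height_m, wood_density_g_cm3,
             coefficients: AllometryCoefficients = _DEFAULT):
    """Aboveground dry biomass (kg) of a tree or palm.

    The pantropical model ``AGB = a · (ρ D² H)^b`` (Chave et al. 2014;
    a = 0.0673, b = 0.976) with D the dbh in cm, H the height in m and
    ρ the wood density in g cm⁻³.  Strictly increasing in each argument
    and a function of the compound driver ρD²H only.

    Accepts scalars or arrays (broadcast).
    """
    _check_positive(dbh_cm=dbh_cm, height_m=height_m,
                    wood_density_g_cm3=wood_density_g_cm3)
    driver = (np.asarray(wood_density_g_cm3, dtype=float)
              * np.asarray(dbh_cm, dtype=float) ** 2
              * np.asarray(height_m, dtype=float))
    out = coefficients.tree_a * driver ** coefficients.tree_b
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def agb_tree_fern_g(dbh_cm, coefficients: AllometryCoefficients = _DEFAULT):
    """Tree-fern aboveground dry biomass in grams, ``a · D^b``."""
    _check_positive(dbh_cm=dbh_cm)
    out = coefficients.fern_a * np.asarray(dbh_cm, dtype=float) ** coefficients.fern_b
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def agb_tree_fern(dbh_cm, coefficients: AllometryCoefficients = _DEFAULT):
    """Tree-fern aboveground dry biomass converted to kg."""
    out = agb_tree_fern_g(dbh_cm, coefficients)
    return out / 1000.0


def agb_abaca(dbh_cm, coefficients: AllometryCoefficients = _DEFAULT):
    """Abaca (Musa textilis) aboveground dry biomass (kg), ``a · D^b``."""
    _check_positive(dbh_cm=dbh_cm)
    out = coefficients.abaca_a * np.asarray(dbh_cm, dtype=float) ** coefficients.abaca_b
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def cwd_volume(diameter_cm, length_m):
    """Volume (m³) of a coarse-woody-debris piece.

    Solid cylinder on the measured in-transect length:
    ``V = π (D/100)² L / 4``. One diameter per piece; no taper or
    line-intersect correction.
    """
    _check_positive(diameter_cm=diameter_cm, length_m=length_m)
    d_m = np.asarray(diameter_cm, dtype=float) / 100.0
    out = math.pi * d_m ** 2 * np.asarray(length_m, dtype=float) / 4.0
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def cwd_dry_mass(diameter_cm, length_m, decay_class: str,
                 table: DecayDensityTable | None = None):
    """Dry mass (kg) of a dead-wood piece: cylinder volume × the decay
    class's wood density (g cm⁻³ ≡ Mg m⁻³, hence × 1000 to kg)."""
    table = table or DecayDensityTable()
    rho = table.density(decay_class)  # raises on unknown class
    vol = cwd_volume(diameter_cm, length_m)
    out = np.asarray(vol) * rho * 1000.0
    return float(out) if np.isscalar(out) or out.ndim == 0 else out
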