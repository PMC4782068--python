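"""Configurable parameter tables: allometric coefficients, wood-density
tables, carbon fractions and size-class edges.

All equation coefficients and conversion constants used by the pipeline
live here so they are auditable and overridable from a YAML file without
code changes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = [
    "AllometryCoefficients",
    "DecayDensityTable",
    "CarbonFractions",
    "SizeClassEdges",
    "AnalysisConfig",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class AllometryCoefficients:
    """Power-law coefficients for the three live-biomass models.

    The tree/palm model is the pantropical diameter-height-density model
    of Chave et al. (2014), ``AGB_kg = a · (ρ D² H)^b``.  The tree-fern
    (Stanley et al.; output in grams) and Abaca (Armecin & Coseco; output
    in kilograms) models are single-predictor power laws in diameter,
    ``AGB = a · D^b``.
    """

    tree_a: float = 0.0673
    tree_b: float = 0.976
    fern_a: float = 31.6   # grams per cm^fern_b
    fern_b: float = 2.5
    abaca_a: float = 0.08  # kg per cm^abaca_b
    abaca_b: float = 1.9

    def __post_init__(self) -> None:
        for name in ("tree_a", "tree_b", "fern_a", "fern_b", "abaca_a", "abaca_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"allometric coefficient {name} must be > 0")


@dataclass(frozen=True)
class DecayDensityTable:
    """Wood density (g cm⁻³) of coarse dead wood by decay class.

    Densities must decrease with decay progression:
    fresh > moderate > high > burnt > 0.
    """

    fresh: float = 0.48
    moderate: float = 0.35
    high: float = 0.25
    burnt: float = 0.19

    def __post_init__(self) -> None:
        if not (self.fresh > self.moderate > self.high > self.burnt > 0):
            raise ValueError(
                "decay densities must satisfy fresh > moderate > high > burnt > 0"
            )

    def density(self, decay_class: str) -> float:
        try:
            return getattr(self, decay_class)
        except AttributeError:
            raise ValueError(f"unknown decay class: {decay_class!r}") from None


@dataclass(frozen=True)
class CarbonFractions:
    """Carbon content as a proportion of dry mass, per biomass component.

    Trees/palms and tree ferns use 0.50; Abaca uses 0.473.  Dead-wood,
    litter and undergrowth fractions default to 0.50 and may be
    overridden with locally measured values.
    """

    tree: float = 0.50
    fern: float = 0.50
    abaca: float = 0.473
    cwd_fresh: float = 0.50
    cwd_moderate: float = 0.50
    cwd_high: float = 0.50
    cwd_burnt: float = 0.50
    litter: float = 0.50
    undergrowth: float = 0.50

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not (0 < value <= 1):
                raise ValueError(f"carbon fraction {name} must be in (0, 1]")

    def cwd(self, decay_class: str) -> float:
        try:
            return getattr(self, f"cwd_{decay_class}")
        except AttributeError:
            raise ValueError(f"unknown decay class: {decay_class!r}") from None


@dataclass(frozen=True)
class SizeClassEdges:
    """Left edges of the dbh (cm) and height (m) classes used in the
    living-woody-biomass breakdowns; the last class is open above."""

    dbh_cm: tuple[float, ...] = (5.0, 10.0, 30.0, 50.0)
    height_m: tuple[float, ...] = (0.0, 10.0, 30.0, 50.0)

    def __post_init__(self) -> None:
        for edges in (self.dbh_cm, self.height_m):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError("size-class edges must be strictly increasing")

    @staticmethod
    def labels(edges: tuple[float, ...]) -> list[str]:
        out = [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
        out.append(f">={edges[-1]:g}")
        return out


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of every tunable parameter table plus analysis thresholds."""

    coefficients: AllometryCoefficients = field(default_factory=AllometryCoefficients)
    decay_densities: DecayDensityTable = field(default_factory=DecayDensityTable)
    carbon_fractions: CarbonFractions = field(default_factory=CarbonFractions)
    size_classes: SizeClassEdges = field(default_factory=SizeClassEdges)
    default_wood_density_g_cm3: float = 0.57
    delta_aicc_threshold: float = 4.0
    collinearity_threshold: float = 0.7
    alpha: float = 0.05


def _as_plain(obj):
    d = asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Serialise an :class:`AnalysisConfig` to YAML."""
    payload = {
        "coefficients": _as_plain(config.coefficients),
        "decay_densities": _as_plain(config.decay_densities),
        "carbon_fractions": _as_plain(config.carbon_fractions),
        "size_classes": _as_plain(config.size_classes),
        "default_wood_density_g_cm3": config.default_wood_density_g_cm3,
        "delta_aicc_threshold": config.delta_aicc_threshold,
        "collinearity_threshold": config.collinearity_threshold,
        "alpha": config.alpha,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML; absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    sc = raw.get("size_classes", {})
    if sc:
        sc = {k: tuple(v) for k, v in sc.items()}
    return AnalysisConfig(
        coefficients=AllometryCoefficients(**raw.get("coefficients", {})),
        decay_densities=DecayDensityTable(**raw.get("decay_densities", {})),
        carbon_fractions=CarbonFractions(**raw.get("carbon_fractions", {})),
        size_classes=SizeClassEdges(**sc) if sc else SizeClassEdges(),
        default_wood_density_g_cm3=raw.get("default_wood_density_g_cm3", 0.57),
        delta_aicc_threshold=raw.get("delta_aicc_threshold", 4.0),
        collinearity_threshold=raw.get("collinearity_threshold", 0.7),
        alpha=raw.get("alpha", 0.05),
    )
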