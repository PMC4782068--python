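"""Forest-inventory data model: schemas, validation and CSV round-trip.

An :class:`Inventory` bundles the five census tables of the sampling
design — a site table plus live stems, other living stems (tree ferns
and Abaca), dead-wood pieces and quadrat dry-mass samples — as pandas
DataFrames with fixed column schemas and units:

* diameters in cm, heights and lengths in m, wood density in g cm⁻³,
  slope in degrees, quadrat dry mass in grams per 1 m² quadrat;
* the census threshold is 5 cm dbh for every woody record;
* each site samples ``n_transects × transect_length_m × transect_width_m``
  of ground (default 4 × 50 m × 5 m = 0.1 ha before slope correction).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FALLOW_CATEGORIES",
    "GUILDS",
    "ORIGINS",
    "DECAY_CLASSES",
    "STAND_FORMS",
    "OTHER_KINDS",
    "QUADRAT_COMPONENTS",
    "InventoryError",
    "SchemaError",
    "ReferentialError",
    "ValidationError",
    "Inventory",
    "read_inventory",
    "write_inventory",
    "lookup_wood_density",
]

#: Fallow-age categories (years since abandonment) plus old-growth control.
CATEGORIES = ("SA0_5", "SA6_10", "SA11_20", "SA21_30", "OG")
FALLOW_CATEGORIES = CATEGORIES[:-1]

GUILDS = ("pioneer", "secondary", "climax")
ORIGINS = ("native", "endemic", "exotic")
DECAY_CLASSES = ("fresh", "moderate", "high", "burnt")
STAND_FORMS = ("standing", "downed")
OTHER_KINDS = ("tree_fern", "abaca")
QUADRAT_COMPONENTS = ("litter", "undergrowth")

DBH_THRESHOLD_CM = 5.0

SITE_COLUMNS = [
    "site_id", "category", "fallow_age_yr", "slope_deg", "patch_size_ha",
    "distance_m", "soc_pct", "elevation_m", "lai",
    "n_transects", "transect_length_m", "transect_width_m",
]
LIVE_STEM_COLUMNS = [
    "site_id", "transect_id", "species_name", "genus", "dbh_cm", "height_m",
    "wood_density_g_cm3", "guild", "origin",
]
OTHER_LIVING_COLUMNS = ["site_id", "transect_id", "kind", "dbh_cm"]
DEAD_WOOD_COLUMNS = [
    "site_id", "transect_id", "diameter_cm", "length_in_transect_m",
    "stand_form", "decay_class",
]
QUADRAT_COLUMNS = [
    "site_id", "transect_id", "component", "dry_mass_g", "carbon_fraction",
]

#: table name -> (filename, required columns)
TABLE_FILES = {
    "sites": ("sites.csv", SITE_COLUMNS),
    "live_stems": ("live_stems.csv", LIVE_STEM_COLUMNS),
    "other_living": ("other_living.csv", OTHER_LIVING_COLUMNS),
    "dead_wood": ("dead_wood.csv", DEAD_WOOD_COLUMNS),
    "quadrats": ("quadrats.csv", QUADRAT_COLUMNS),
}


class InventoryError(ValueError):
    """Base class for inventory schema/validation failures."""


class SchemaError(InventoryError):
    """A table is missing a required column."""


class ReferentialError(InventoryError):
    """A census record references an unknown site."""


class ValidationError(InventoryError):
    """A record violates a stated field invariant."""


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Inventory:
    """Validated container for the five census tables."""

    sites: pd.DataFrame = field(default_factory=lambda: _empty(SITE_COLUMNS))
    live_stems: pd.DataFrame = field(default_factory=lambda: _empty(LIVE_STEM_COLUMNS))
    other_living: pd.DataFrame = field(default_factory=lambda: _empty(OTHER_LIVING_COLUMNS))
    dead_wood: pd.DataFrame = field(default_factory=lambda: _empty(DEAD_WOOD_COLUMNS))
    quadrats: pd.DataFrame = field(default_factory=lambda: _empty(QUADRAT_COLUMNS))

    # -- validation ----------------------------------------------------

    def validate(self) -> "Inventory":
        """Check schemas, field invariants and referential integrity.

        Returns self so construction can be chained; raises a subclass of
        :class:`InventoryError` naming the offending column or rows.
        """
        for name, (_, cols) in TABLE_FILES.items():
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} is missing column(s) {missing}")

        self._validate_sites()
        site_ids = set(self.sites["site_id"])
        for name in ("live_stems", "other_living", "dead_wood", "quadrats"):
            df = getattr(self, name)
            dangling = sorted(set(df["site_id"]) - site_ids)
            if dangling:
                raise ReferentialError(
                    f"table {name!r} references unknown site_id(s) {dangling}"
                )
        self._validate_live_stems()
        self._validate_other_living()
        self._validate_dead_wood()
        self._validate_quadrats()
        return self

    def _validate_sites(self) -> None:
        df = self.sites
        if df["site_id"].duplicated().any():
            dupes = sorted(df.loc[df["site_id"].duplicated(), "site_id"])
            raise ValidationError(f"duplicate site_id(s) {dupes}")
        bad_cat = df.loc[~df["category"].isin(CATEGORIES)]
        if len(bad_cat):
            raise ValidationError(
                f"unknown category in rows {list(bad_cat.index)}: "
                f"{sorted(set(bad_cat['category']))}"
            )
        age = pd.to_numeric(df["fallow_age_yr"], errors="coerce")
        og = df["category"] == "OG"
        if age[og].notna().any():
            raise ValidationError("old-growth sites must not declare a fallow age")
        if age[~og].isna().any():
            rows = list(df.index[~og & age.isna()])
            raise ValidationError(f"fallow sites missing fallow_age_yr in rows {rows}")
        checks = {
            "slope_deg": lambda s: (s >= 0) & (s < 90),
            "patch_size_ha": lambda s: s > 0,
            "distance_m": lambda s: s >= 0,
            "soc_pct": lambda s: (s >= 0) & (s <= 100),
            "lai": lambda s: s >= 0,
            "n_transects": lambda s: s > 0,
            "transect_length_m": lambda s: s > 0,
            "transect_width_m": lambda s: s > 0,
        }
        for col, ok in checks.items():
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~(vals.notna() & np.isfinite(vals) & ok(vals))
            if bad.any():
                raise ValidationError(
                    f"sites.{col} invalid in rows {list(df.index[bad])}"
                )
        elev = pd.to_numeric(df["elevation_m"], errors="coerce")
        if (~np.isfinite(elev)).any():
            raise ValidationError("sites.elevation_m must be finite")

    def _require(self, name: str, col: str, mask: pd.Series) -> None:
        if (~mask).any():
            df = getattr(self, name)
            raise ValidationError(
                f"{name}.{col} invalid in rows {list(df.index[~mask])}"
            )

    def _validate_live_stems(self) -> None:
        df = self.live_stems
        if not len(df):
            return
        dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
        self._require("live_stems", "dbh_cm", dbh >= DBH_THRESHOLD_CM)
        h = pd.to_numeric(df["height_m"], errors="coerce")
        self._require("live_stems", "height_m", h > 0)
        rho = pd.to_numeric(df["wood_density_g_cm3"], errors="coerce")
        self._require(
            "live_stems", "wood_density_g_cm3",
            rho.isna() | ((rho > 0) & (rho < 1.5)),
        )
        self._require("live_stems", "guild", df["guild"].isin(GUILDS))
        self._require("live_stems", "origin", df["origin"].isin(ORIGINS))

    def _validate_other_living(self) -> None:
        df = self.other_living
        if not len(df):
            return
        self._require("other_living", "kind", df["kind"].isin(OTHER_KINDS))
        dbh = pd.to_numeric(df["dbh_cm"], errors="coerce")
        self._require("other_living", "dbh_cm", dbh >= DBH_THRESHOLD_CM)

    def _validate_dead_wood(self) -> None:
        df = self.dead_wood
        if not len(df):
            return
        d = pd.to_numeric(df["diameter_cm"], errors="coerce")
        self._require("dead_wood", "diameter_cm", d >= DBH_THRESHOLD_CM)
        ln = pd.to_numeric(df["length_in_transect_m"], errors="coerce")
        self._require("dead_wood", "length_in_transect_m", ln > 0)
        self._require("dead_wood", "stand_form", df["stand_form"].isin(STAND_FORMS))
        self._require("dead_wood", "decay_class", df["decay_class"].isin(DECAY_CLASSES))

    def _validate_quadrats(self) -> None:
        df = self.quadrats
        if not len(df):
            return
        self._require(
            "quadrats", "component", df["component"].isin(QUADRAT_COMPONENTS)
        )
        m = pd.to_numeric(df["dry_mass_g"], errors="coerce")
        self._require("quadrats", "dry_mass_g", m >= 0)
        f = pd.to_numeric(df["carbon_fraction"], errors="coerce")
        self._require("quadrats", "carbon_fraction", f.isna() | ((f > 0) & (f <= 1)))

    # -- convenience ---------------------------------------------------

    def site(self, site_id: str) -> pd.Series:
        rows = self.sites.loc[self.sites["site_id"] == site_id]
        if not len(rows):
            raise KeyError(f"unknown site_id {site_id!r}")
        return rows.iloc[0]

    def equals(self, other: "Inventory") -> bool:
        """Field-for-field equality of all five tables (NaN == NaN)."""
        for name, (_, cols) in TABLE_FILES.items():
            a = getattr(self, name)[cols].reset_index(drop=True)
            b = getattr(other, name)[cols].reset_index(drop=True)
            if len(a) != len(b):
                return False
            for c in cols:
                av, bv = a[c], b[c]
                if not (av.isna().to_numpy() == bv.isna().to_numpy()).all():
                    return False
                av, bv = av.dropna(), bv.dropna()
                an = pd.to_numeric(av, errors="coerce")
                bn = pd.to_numeric(bv, errors="coerce")
                num = (an.notna() & bn.notna()).to_numpy()
                if not (an.to_numpy()[num] == bn.to_numpy()[num]).all():
                    return False
                if not (av.astype(str).to_numpy()[~num]
                        == bv.astype(str).to_numpy()[~num]).all():
                    return False
        return True


def read_inventory(directory: str | Path, *, validate: bool = True) -> Inventory:
    """Read the five census CSVs from ``directory`` into an Inventory.

    Expects UTF-8 CSVs named ``sites.csv``, ``live_stems.csv``,
    ``other_living.csv``, ``dead_wood.csv`` and ``quadrats.csv`` with
    header rows declaring the documented schemas.
    """
    directory = Path(directory)
    tables = {}
    for name, (fname, cols) in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"missing inventory table {path}")
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{fname} is missing column(s) {missing}")
        tables[name] = df[cols]
    inv = Inventory(**tables)
    return inv.validate() if validate else inv


def write_inventory(inventory: Inventory, directory: str | Path) -> None:
    """Write the five census tables as UTF-8 CSVs; round-trips exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, (fname, cols) in TABLE_FILES.items():
        df = getattr(inventory, name)
        # shortest round-trip float formatting so read(write(x)) == x exactly
        df.to_csv(directory / fname, index=False, columns=list(cols),
                  encoding="utf-8", float_format=lambda v: repr(float(v)))


def lookup_wood_density(
    species_name: str,
    genus: str,
    density_table: Mapping[str, object],
    *,
    default: float = 0.57,
) -> float:
    """Resolve a wood density (g cm⁻³) for a species.

    Resolution order: exact species entry; arithmetic mean of the genus
    entries; the configured global default. Always resolves.

    ``density_table`` maps species name -> density and genus name -> a
    sequence of densities for species of that genus.
    """
    value = density_table.get(species_name)
    if value is not None and not isinstance(value, (list, tuple, np.ndarray)):
        return float(value)
    genus_values = density_table.get(genus)
    if genus_values is not None:
        seq = (
            list(genus_values)
            if isinstance(genus_values, (list, tuple, np.ndarray))
            else [genus_values]
        )
        if seq:
            return float(np.mean([float(v) for v in seq]))
    return float(default)
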