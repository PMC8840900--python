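"""Point-count survey ingestion: raw count tables → per-sample biomass rows.

Surveys arrive as delimited text with one row per observed species per point
visit.  Two national conventions are supported: ``pair_counts`` (the census
unit is a breeding pair; counts are doubled to individuals) and
``individual_counts`` (each bird counted as such, possibly over two breeding
periods per season that are summed into one annual value).  After guild
filtering (raptors, grouse, waders and waterfowl are surveyed poorly by
point counts and are excluded, as are non-forest species), counts are
converted to biomass (count × species body mass, g) and split into the
indicator group (titmice, Paridae), the target group (all other forest
birds), and optionally a held-out control group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, SpeciesLookupError, StateError

__all__ = [
    "DEFAULT_AREA_KM2",
    "PointCountTable",
    "read_point_counts",
    "read_traits",
    "read_locations",
    "pairs_to_individuals",
    "merge_breeding_periods",
    "apply_guild_filters",
    "build_samples",
]

logger = logging.getLogger(__name__)

DEFAULT_AREA_KM2 = 0.031  # circular point-count area

RECORD_KEY = ["site_id", "point_id", "year", "period", "species_code"]
RECORD_COLUMNS = RECORD_KEY + ["count", "habitat_code"]
TRAIT_COLUMNS = ["species_code", "body_mass", "is_titmouse", "is_excluded_guild", "is_forest"]


@dataclass
class PointCountTable:
    """Point-count records plus the census-unit mode they are expressed in."""

    records: pd.DataFrame
    country_mode: str  # "pair_counts" | "individual_counts"

    def __post_init__(self):
        if self.country_mode not in ("pair_counts", "individual_counts"):
            raise ConfigurationError(f"unknown country_mode {self.country_mode!r}")

    def __len__(self) -> int:
        return len(self.records)


def _aggregate_duplicates(df: pd.DataFrame, where: str) -> pd.DataFrame:
    dup = df.duplicated(RECORD_KEY)
    if dup.any():
        logger.warning("%s: summing %d duplicate-key rows", where, int(dup.sum()))
        df = (
            df.groupby(RECORD_KEY, as_index=False, sort=False)
            .agg(count=("count", "sum"), habitat_code=("habitat_code", "first"))
        )
    return df


def read_point_counts(path, dialect: dict, country_mode: str = "individual_counts",
                      sep: str | None = None) -> PointCountTable:
    """Read a delimited count file using a column-mapping dialect.

    ``dialect`` maps canonical names (site_id, point_id, year, period,
    species_code, count, habitat_code) to the file's column headers; period
    and habitat_code are optional (defaulting to 1 and "" respectively).
    Duplicate keys are summed with a logged warning.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = ["site_id", "point_id", "year", "species_code", "count"]
    missing = [k for k in required if k not in dialect]
    if missing:
        raise ConfigurationError(f"dialect missing mappings for: {missing}")
    absent = [v for v in dialect.values() if v not in df.columns]
    if absent:
        raise ConfigurationError(f"mapped columns not in file {path}: {absent}")
    out = pd.DataFrame({k: df[v] for k, v in dialect.items()})
    if "period" not in out.columns:
        out["period"] = 1
    if "habitat_code" not in out.columns:
        out["habitat_code"] = ""
    bad = pd.to_numeric(out["count"], errors="coerce")
    nonint = bad.isna() | (bad != np.floor(bad)) | (bad < 0)
    if nonint.any():
        row = int(np.flatnonzero(nonint.to_numpy())[0])
        raise DataError(f"non-integer or negative count at data row {row} of {path}")
    out["count"] = bad.astype(int)
    out["year"] = out["year"].astype(int)
    out["period"] = out["period"].astype(int)
    if not out["period"].isin([1, 2]).all():
        raise DataError("period must be 1 or 2")
    out = _aggregate_duplicates(out[RECORD_COLUMNS], str(path))
    return PointCountTable(records=out.reset_index(drop=True), country_mode=country_mode)


def read_traits(path, sep: str | None = None) -> pd.DataFrame:
    """Read the species trait table (body mass, guild and group flags)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"trait table missing columns: {missing}")
    df = df[TRAIT_COLUMNS].copy()
    for c in ("is_titmouse", "is_excluded_guild", "is_forest"):
        df[c] = df[c].astype(bool)
    if (df["body_mass"] <= 0).any():
        raise DataError("body masses must be positive")
    if (df["is_titmouse"] & df["is_excluded_guild"]).any():
        raise DataError("a species cannot be both titmouse and excluded guild")
    return df.set_index("species_code", verify_integrity=True)


def read_locations(path, sep: str | None = None) -> pd.DataFrame:
    """Read planar (km) coordinates, one row per (site_id, point_id)."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in ("site_id", "point_id", "x_km", "y_km") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"location table missing columns: {missing}")
    if df.duplicated(["site_id", "point_id"]).any():
        raise DataError("locations must be unique per (site_id, point_id)")
    return df


def pairs_to_individuals(table: PointCountTable) -> PointCountTable:
    """Double pair counts to individuals (census unit: pair → 2 birds)."""
    if table.country_mode != "pair_counts":
        raise StateError("pairs_to_individuals requires pair_counts mode")
    rec = table.records.copy()
    rec["count"] = rec["count"] * 2
    return PointCountTable(records=rec, country_mode="individual_counts")


def merge_breeding_periods(table: PointCountTable) -> PointCountTable:
    """Sum the two within-season sampling periods into one annual record set."""
    if table.country_mode != "individual_counts":
        raise StateError("merge_breeding_periods requires individual_counts mode")
    rec = table.records.copy()
    rec["period"] = 1
    rec = (
        rec.groupby(RECORD_KEY, as_index=False, sort=False)
        .agg(count=("count", "sum"), habitat_code=("habitat_code", "first"))
    )
    return PointCountTable(records=rec[RECORD_COLUMNS], country_mode=table.country_mode)


def _check_species(records: pd.DataFrame, traits: pd.DataFrame) -> None:
    unknown = set(records["species_code"]) - set(traits.index)
    if unknown:
        raise SpeciesLookupError(unknown)


def apply_guild_filters(table: PointCountTable, traits: pd.DataFrame) -> PointCountTable:
    """Drop excluded guilds (raptors/grouse/waders/waterfowl) and non-forest species."""
    rec = table.records
    _check_species(rec, traits)
    tr = traits.loc[rec["species_code"]]
    keep = (~tr["is_excluded_guild"].to_numpy()) & tr["is_forest"].to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("guild/forest filter removed %d of %d records", n_drop, len(rec))
    return PointCountTable(records=rec[keep].reset_index(drop=True),
                           country_mode=table.country_mode)


def build_samples(
    table: PointCountTable,
    traits: pd.DataFrame,
    locations: pd.DataFrame,
    area: float = DEFAULT_AREA_KM2,
    control_species: set[str] | None = None,
) -> pd.DataFrame:
    """Per point-year biomass rows: target ``b``, indicator ``tit``, optional ``control``.

    ``b`` sums count × body mass over non-titmouse forest species (minus any
    control species, whose biomass goes to ``control``); ``tit`` sums over
    titmice.  Point-years observed in the records but with no birds in a
    group get 0 for that group.  Samples carry the planar location of their
    point and the configured sampled area.
    """
    if table.country_mode != "individual_counts":
        raise StateError("build_samples requires individual_counts mode")
    rec = table.records
    _check_species(rec, traits)
    control_species = set(control_species or ())
    tit_set = set(traits.index[traits["is_titmouse"]])
    overlap = control_species & tit_set
    if overlap:
        raise ConfigurationError(f"control species overlap titmice: {sorted(overlap)}")

    tr = traits.loc[rec["species_code"]]
    biomass = rec["count"].to_numpy() * tr["body_mass"].to_numpy()
    is_tit = tr["is_titmouse"].to_numpy()
    in_ctrl = rec["species_code"].isin(control_species).to_numpy()

    df = rec[["site_id", "point_id", "year", "habitat_code"]].copy()
    df["tit"] = np.where(is_tit, biomass, 0.0)
    df["control"] = np.where(~is_tit & in_ctrl, biomass, 0.0)
    df["b"] = np.where(~is_tit & ~in_ctrl, biomass, 0.0)
    agg = df.groupby(["site_id", "point_id", "year"], as_index=False, sort=True).agg(
        b=("b", "sum"), tit=("tit", "sum"), control=("control", "sum"),
        habitat_class=("habitat_code", "first"),
    )
    agg = agg.merge(locations[["site_id", "point_id", "x_km", "y_km"]],
                    on=["site_id", "point_id"], how="left", validate="many_to_one")
    if agg[["x_km", "y_km"]].isna().any().any():
        miss = agg.loc[agg["x_km"].isna(), ["site_id", "point_id"]].drop_duplicates()
        raise DataError(f"no location for {len(miss)} (site, point) pairs")
    agg["a"] = float(area)
    if not control_species:
        agg = agg.drop(columns="control")
    agg.insert(0, "sample_id", np.arange(len(agg)))
    return agg
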