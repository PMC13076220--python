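"""Isotope record schema, reading/validation, and functional-group assignment.

The pipeline's atomic input is one animal sample with paired carbon and
nitrogen stable-isotope values in delta notation (per mil vs VPDB for
δ13C and vs atmospheric N2 for δ15N), a site identifier, a high-rank
taxon (e.g. "Collembola"), optional finer taxonomy, and the site's
climate-zone and land-use strata.  High-rank soil taxa are trophically
consistent enough to be assigned to one of five functional groups
(herbivore, detritivore, microbivore, predator, mixed feeder), which is
the grouping level at which niche metrics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CLIMATE_ZONES",
    "LAND_USES",
    "FUNCTIONAL_GROUPS",
    "DEFAULT_GROUP_MAP",
    "CANONICAL_COLUMNS",
    "REQUIRED_COLUMNS",
    "IsotopeRecord",
    "FunctionalGroupMap",
    "ReadReport",
    "ReadConfig",
    "SchemaError",
    "TaxonLookupError",
    "delta_from_ratios",
    "assign_functional_group",
    "read_records",
    "write_records",
    "validate_records",
]

CLIMATE_ZONES = frozenset({"subarctic", "temperate", "subtropical", "tropical"})
LAND_USES = frozenset({"woodland", "agriculture", "grassland", "other"})
FUNCTIONAL_GROUPS = frozenset(
    {"herbivore", "detritivore", "microbivore", "predator", "mixed"}
)

# Plausible ranges for soil-animal tissue; values outside trigger a warning
# (likely unit or sign errors) but are retained.
D13C_PLAUSIBLE = (-60.0, 10.0)
D15N_PLAUSIBLE = (-15.0, 30.0)

CANONICAL_COLUMNS = (
    "record_id",
    "site_id",
    "climate_zone",
    "land_use",
    "taxon",
    "family",
    "genus",
    "species",
    "d13C",
    "d15N",
)
REQUIRED_COLUMNS = (
    "record_id",
    "site_id",
    "climate_zone",
    "land_use",
    "taxon",
    "d13C",
    "d15N",
)

#: High-rank taxon -> functional group.  28 taxa; mixed feeders are the
#: two orders whose member species span herbivory through predation.
DEFAULT_GROUP_MAP: dict[str, str] = {
    # herbivores
    "Hemiptera": "herbivore",
    "Orthoptera": "herbivore",
    "Thysanoptera": "herbivore",
    "Lepidoptera": "herbivore",
    # detritivores (primary decomposers)
    "Lumbricina": "detritivore",
    "Diplopoda": "detritivore",
    "Isopoda": "detritivore",
    "Isoptera": "detritivore",
    "Dermaptera": "detritivore",
    "Blattodea": "detritivore",
    "Gastropoda": "detritivore",
    "Enchytraeidae": "detritivore",
    # microbivores (secondary decomposers)
    "Collembola": "microbivore",
    "Oribatida": "microbivore",
    "Nematoda": "microbivore",
    "Protura": "microbivore",
    "Prostigmata": "microbivore",
    "Psocoptera": "microbivore",
    "Symphyla": "microbivore",
    # predators
    "Araneae": "predator",
    "Chilopoda": "predator",
    "Diplura": "predator",
    "Formicidae": "predator",
    "Mesostigmata": "predator",
    "Opiliones": "predator",
    "Pseudoscorpiones": "predator",
    # mixed feeders
    "Diptera": "mixed",
    "Coleoptera": "mixed",
}

#: Spelling variants accepted for taxon names (normalized -> canonical).
DEFAULT_TAXON_ALIASES: dict[str, str] = {
    "mesotigmata": "Mesostigmata",
}


class SchemaError(ValueError):
    """Input table is missing required columns or is otherwise malformed."""


class TaxonLookupError(KeyError):
    """A taxon name has no functional-group assignment."""

    def __init__(self, taxon: str):
        super().__init__(taxon)
        self.taxon = taxon

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"taxon {self.taxon!r} has no functional-group assignment"


def delta_from_ratios(r_sample: float, r_standard: float) -> float:
    """Convert a raw heavy/light isotope ratio to delta notation (per mil).

    delta = (R_sample / R_standard - 1) * 1000, relative to the
    international standard (VPDB for 13C/12C, atmospheric N2 for 15N/14N).

    Parameters
    ----------
    r_sample : float
        Measured isotope ratio of the sample (>= 0).
    r_standard : float
        Isotope ratio of the standard (> 0).
    """
    if not (r_standard > 0):
        raise ValueError(f"standard ratio must be positive, got {r_standard!r}")
    if r_sample < 0:
        raise ValueError(f"sample ratio must be non-negative, got {r_sample!r}")
    return (r_sample / r_standard - 1.0) * 1000.0


@dataclass(frozen=True)
class IsotopeRecord:
    """One animal sample's paired isotope values with site and taxonomy."""

    record_id: str
    site_id: str
    climate_zone: str
    land_use: str
    taxon: str
    d13C: float
    d15N: float
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    functional_group: str | None = None

    def __post_init__(self):
        if not (math.isfinite(self.d13C) and math.isfinite(self.d15N)):
            raise ValueError("d13C and d15N must both be finite")
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(f"unknown climate_zone {self.climate_zone!r}")
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land_use {self.land_use!r}")


class FunctionalGroupMap:
    """Case-insensitive, whitespace-tolerant taxon -> functional group lookup."""

    def __init__(
        self,
        entries: Mapping[str, str] | None = None,
        aliases: Mapping[str, str] | None = None,
    ):
        entries = dict(entries) if entries is not None else dict(DEFAULT_GROUP_MAP)
        bad = {g for g in entries.values()} - FUNCTIONAL_GROUPS
        if bad:
            raise ValueError(f"unknown functional groups in map: {sorted(bad)}")
        self.entries = entries
        self.aliases = dict(DEFAULT_TAXON_ALIASES)
        if aliases:
            self.aliases.update({k.strip().lower(): v for k, v in aliases.items()})
        self._norm = {k.strip().lower(): v for k, v in entries.items()}

    def canonical_taxon(self, taxon: str) -> str:
        key = taxon.strip().lower()
        return self.aliases.get(key, taxon.strip())

    def lookup(self, taxon: str) -> str:
        key = self.canonical_taxon(taxon).strip().lower()
        try:
            return self._norm[key]
        except KeyError:
            raise TaxonLookupError(taxon) from None

    def __contains__(self, taxon: str) -> bool:
        return self.canonical_taxon(taxon).strip().lower() in self._norm

    def taxa(self) -> list[str]:
        return sorted(self.entries)

    def taxa_in_group(self, group: str) -> list[str]:
        return sorted(t for t, g in self.entries.items() if g == group)


def assign_functional_group(
    taxon: str, group_map: FunctionalGroupMap | None = None
) -> str:
    """Return the functional group of a high-rank taxon (deterministic lookup)."""
    group_map = group_map or FunctionalGroupMap()
    return group_map.lookup(taxon)


@dataclass
class ReadReport:
    """Counts of retained and rejected rows, with reasons."""

    n_read: int = 0
    n_retained: int = 0
    rejected: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def reject(self, reason: str, count: int = 1) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + count

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())


@dataclass
class ReadConfig:
    """Declarative reader configuration.

    column_aliases maps file column names to the canonical schema names;
    group_overrides extends or overrides the default taxon->group map;
    strict controls unmappable-taxon behaviour (error vs exclude+count).
    """

    column_aliases: dict[str, str] = field(default_factory=dict)
    group_overrides: dict[str, str] = field(default_factory=dict)
    taxon_aliases: dict[str, str] = field(default_factory=dict)
    strict: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReadConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            column_aliases=raw.get("column_aliases", {}) or {},
            group_overrides=raw.get("group_overrides", {}) or {},
            taxon_aliases=raw.get("taxon_aliases", {}) or {},
            strict=bool(raw.get("strict", True)),
        )

    def build_group_map(self) -> FunctionalGroupMap:
        entries = dict(DEFAULT_GROUP_MAP)
        entries.update(self.group_overrides)
        return FunctionalGroupMap(entries, aliases=self.taxon_aliases)


def _separator(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_records(
    path: str | Path,
    group_map: FunctionalGroupMap | None = None,
    config: ReadConfig | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read and validate a CSV/TSV isotope table.

    Returns a DataFrame with canonical columns plus ``functional_group``,
    and a :class:`ReadReport` counting rejected rows by reason.  Rows with
    missing/non-finite isotope values or invalid stratum labels are always
    rejected; unmappable taxa raise in strict mode and are excluded (and
    counted) in lenient mode.  Out-of-range isotope values are retained
    with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    config = config or ReadConfig()
    if group_map is None:
        group_map = config.build_group_map()

    df = pd.read_csv(path, sep=_separator(path), dtype=str, keep_default_na=False)
    df = df.rename(columns=config.column_aliases)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in ("family", "genus", "species"):
        if col not in df.columns:
            df[col] = ""

    report = ReadReport(n_read=len(df))
    df = df[list(CANONICAL_COLUMNS)].copy()
    for col in ("d13C", "d15N"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok_iso = np.isfinite(df["d13C"]) & np.isfinite(df["d15N"])
    if (~ok_iso).any():
        report.reject("missing isotope value", int((~ok_iso).sum()))
        df = df[ok_iso]

    df["climate_zone"] = df["climate_zone"].str.strip().str.lower()
    df["land_use"] = df["land_use"].str.strip().str.lower()
    ok_strata = df["climate_zone"].isin(CLIMATE_ZONES) & df["land_use"].isin(LAND_USES)
    if (~ok_strata).any():
        report.reject("invalid climate_zone or land_use", int((~ok_strata).sum()))
        df = df[ok_strata]

    # taxon canonicalization and functional-group annotation
    canon = df["taxon"].map(group_map.canonical_taxon)
    mappable = canon.map(lambda t: t in group_map)
    if (~mappable).any():
        unknown = sorted(canon[~mappable].unique())
        if config.strict:
            raise TaxonLookupError(unknown[0])
        report.reject("unmappable taxon", int((~mappable).sum()))
        df, canon = df[mappable], canon[mappable]
    df = df.assign(taxon=canon)
    df["functional_group"] = df["taxon"].map(group_map.lookup)

    lo, hi = D13C_PLAUSIBLE
    n_odd = int(((df["d13C"] < lo) | (df["d13C"] > hi)).sum())
    if n_odd:
        report.warnings.append(f"{n_odd} records with d13C outside [{lo}, {hi}] permil")
    lo, hi = D15N_PLAUSIBLE
    n_odd = int(((df["d15N"] < lo) | (df["d15N"] > hi)).sum())
    if n_odd:
        report.warnings.append(f"{n_odd} records with d15N outside [{lo}, {hi}] permil")

    report.n_retained = len(df)
    return df.reset_index(drop=True), report


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write records to CSV/TSV with canonical column order."""
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep=_separator(path), index=False)


def validate_records(df: pd.DataFrame) -> None:
    """Raise if a record table violates the schema invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if not np.isfinite(df[["d13C", "d15N"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite isotope values present")
    bad_cz = set(df["climate_zone"]) - CLIMATE_ZONES
    bad_lu = set(df["land_use"]) - LAND_USES
    if bad_cz or bad_lu:
        raise ValueError(f"invalid strata: climate={sorted(bad_cz)} land_use={sorted(bad_lu)}")


def records_to_frame(records: Iterable[IsotopeRecord]) -> pd.DataFrame:
    """Convert IsotopeRecord objects to the canonical DataFrame layout."""
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows)
    return df[[c for c in list(CANONICAL_COLUMNS) + ["functional_group"] if c in df.columns]]
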