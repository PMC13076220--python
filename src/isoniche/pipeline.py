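"""Per-site, per-group orchestration of the niche metrics.

For every site x functional group passing the minimum-sample filter the
pipeline computes the group-level ellipse area (pooling all individual
records of the group at that site), the per-taxon ellipse areas whose
unweighted mean is the niche-*expansion* indicator, and the mean
pairwise centroid distance between taxa — the niche-*partitioning*
indicator.  The same machinery runs at coarser or finer taxonomic
resolution (high-rank taxon, family, genus, species) by swapping the
column that defines "taxon".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .niche_metrics import trophic_dissimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "RESOLUTION_LEVELS",
    "METRIC_COLUMNS",
    "ExclusionReport",
    "compute_site_metrics",
    "subset_for_contrasts",
    "decomposition_table",
]

#: resolution level -> record column holding the taxon identity
RESOLUTION_LEVELS = {
    "taxon": "taxon",  # high-rank taxon (default)
    "family": "family",
    "genus": "genus",
    "species": "species",
}

METRIC_COLUMNS = [
    "site_id",
    "climate_zone",
    "land_use",
    "functional_group",
    "n_samples",
    "taxon_richness",
    "family_richness",
    "group_seac",
    "mean_taxon_seac",
    "dissimilarity",
    "sd13C",
    "sd15N",
    "mean13C",
    "mean15N",
    "var13C",
    "var15N",
    "cov1315",
]


@dataclass
class ExclusionReport:
    """Filter bookkeeping: which site x group (or taxon) cells were dropped."""

    excluded_groups: list[tuple] = field(default_factory=list)  # (site, group, n)
    excluded_taxa: list[tuple] = field(default_factory=list)  # (site, group, taxon, n)
    n_records_missing_rank: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(site_id=s, functional_group=g, taxon="", n=n, level="group")
            for s, g, n in self.excluded_groups
        ] + [
            dict(site_id=s, functional_group=g, taxon=t, n=n, level="taxon")
            for s, g, t, n in self.excluded_taxa
        ]
        return pd.DataFrame(rows, columns=["site_id", "functional_group", "taxon", "n", "level"])


def _moment_table(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Vectorized per-group count, centroid and sample covariance entries."""
    tmp = df[keys].copy()
    x = df["d13C"].to_numpy(dtype=float)
    y = df["d15N"].to_numpy(dtype=float)
    tmp["_x"], tmp["_y"] = x, y
    tmp["_xx"], tmp["_yy"], tmp["_xy"] = x * x, y * y, x * y
    g = tmp.groupby(keys, sort=True, observed=True).agg(
        n=("_x", "size"),
        sx=("_x", "sum"),
        sy=("_y", "sum"),
        sxx=("_xx", "sum"),
        syy=("_yy", "sum"),
        sxy=("_xy", "sum"),
    )
    n = g["n"].to_numpy(dtype=float)
    mx, my = g["sx"] / n, g["sy"] / n
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.where(n > 1, n - 1, np.nan)
        var_x = (g["sxx"] - n * mx**2) / denom
        var_y = (g["syy"] - n * my**2) / denom
        cov_xy = (g["sxy"] - n * mx * my) / denom
    out = pd.DataFrame(
        {
            "n": g["n"],
            "mean13C": mx,
            "mean15N": my,
            "var13C": var_x.clip(lower=0.0),
            "var15N": var_y.clip(lower=0.0),
            "cov1315": cov_xy,
        }
    )
    return out.reset_index()


def _sea_from_moments(tbl: pd.DataFrame) -> np.ndarray:
    det = tbl["var13C"].to_numpy() * tbl["var15N"].to_numpy() - tbl["cov1315"].to_numpy() ** 2
    return np.pi * np.sqrt(np.clip(det, 0.0, None))


def compute_site_metrics(
    records: pd.DataFrame,
    threshold: int = 5,
    level: str = "taxon",
    centroid_min: int = 2,
    taxon_threshold: int | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Compute the per-site, per-functional-group metrics table.

    Parameters
    ----------
    records : DataFrame
        Validated records with a ``functional_group`` column.
    threshold : int
        Minimum pooled sample count for a site x group ellipse (and, by
        default, for each taxon-level ellipse); must be >= 3.
    level : str
        Taxonomic resolution for the within-group taxa: one of
        ``taxon`` (high-rank), ``family``, ``genus``, ``species``.
        Records lacking the requested rank are excluded at that level.
    centroid_min : int
        Minimum per-taxon n for that taxon's centroid to enter the
        dissimilarity (>= 2 so the centroid is a real mean).
    taxon_threshold : int, optional
        Minimum per-taxon n for the taxon-level SEAc; defaults to
        ``threshold``.

    Returns
    -------
    metrics : DataFrame
        One row per site x functional group passing the filter, columns
        :data:`METRIC_COLUMNS`.  ``mean_taxon_seac`` is NaN when no
        taxon passes the per-taxon filter; ``dissimilarity`` is NaN when
        fewer than two taxa have centroids.
    report : ExclusionReport
    """
    if threshold < 3:
        raise ValueError(f"threshold must be >= 3, got {threshold}")
    if level not in RESOLUTION_LEVELS:
        raise ValueError(f"unknown resolution level {level!r}")
    taxon_threshold = threshold if taxon_threshold is None else taxon_threshold
    if taxon_threshold < 3:
        raise ValueError("taxon_threshold must be >= 3")
    if centroid_min < 2:
        raise ValueError("centroid_min must be >= 2")

    report = ExclusionReport()
    cols = ["site_id", "climate_zone", "land_use", "functional_group"]
    if records.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS), report

    taxon_col = RESOLUTION_LEVELS[level]
    df = records.copy()
    df["_unit"] = df[taxon_col].astype(str).str.strip()
    has_rank = df["_unit"] != ""
    report.n_records_missing_rank = int((~has_rank).sum())
    df = df[has_rank]
    if df.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS), report

    # group level: pooled records per site x functional group
    gtab = _moment_table(df, cols)
    keep = gtab["n"] >= threshold
    for _, row in gtab[~keep].iterrows():
        report.excluded_groups.append((row["site_id"], row["functional_group"], int(row["n"])))
    gtab = gtab[keep].copy()
    if gtab.empty:
        return pd.DataFrame(columns=METRIC_COLUMNS), report
    sea = _sea_from_moments(gtab)
    n = gtab["n"].to_numpy(dtype=float)
    gtab["group_seac"] = sea * (n - 1) / (n - 2)
    gtab["sd13C"] = np.sqrt(gtab["var13C"])
    gtab["sd15N"] = np.sqrt(gtab["var15N"])

    # taxon level within site x group
    ttab = _moment_table(df, cols + ["_unit"])
    tn = ttab["n"].to_numpy(dtype=float)
    tsea = _sea_from_moments(ttab)
    with np.errstate(invalid="ignore"):
        ttab["taxon_seac"] = np.where(tn >= 3, tsea * (tn - 1) / np.where(tn > 2, tn - 2, np.nan), np.nan)
    ttab["passes"] = ttab["n"] >= taxon_threshold
    for _, row in ttab[~ttab["passes"]].iterrows():
        report.excluded_taxa.append(
            (row["site_id"], row["functional_group"], row["_unit"], int(row["n"]))
        )

    agg_rows = []
    for key, sub in ttab.groupby(cols, sort=True, observed=True):
        qual = sub[sub["passes"]]
        mean_taxon_seac = float(qual["taxon_seac"].mean()) if len(qual) else np.nan
        cen_sub = sub[sub["n"] >= centroid_min]
        if len(cen_sub) >= 2:
            diss = trophic_dissimilarity(cen_sub[["mean13C", "mean15N"]].to_numpy())
        else:
            diss = np.nan
        agg_rows.append(
            dict(
                zip(cols, key),
                taxon_richness=int(len(qual)),
                mean_taxon_seac=mean_taxon_seac,
                dissimilarity=diss,
            )
        )
    agg = pd.DataFrame(agg_rows)

    out = gtab.merge(agg, on=cols, how="left")
    out = out.rename(columns={"n": "n_samples"})
    out["taxon_richness"] = out["taxon_richness"].fillna(0).astype(int)

    # covariate for the sampling-effort model: distinct families per cell
    if "family" in df.columns:
        fam = (
            df[df["family"].astype(str).str.strip() != ""]
            .groupby(cols, observed=True)["family"]
            .nunique()
            .rename("family_richness")
            .reset_index()
        )
        out = out.merge(fam, on=cols, how="left")
        out["family_richness"] = out["family_richness"].fillna(0).astype(int)
    else:
        out["family_richness"] = np.nan
    return out[METRIC_COLUMNS].reset_index(drop=True), report


def subset_for_contrasts(
    table: pd.DataFrame,
    climates: set[str] = frozenset({"temperate", "tropical"}),
    land_uses: set[str] = frozenset({"woodland", "agriculture"}),
) -> pd.DataFrame:
    """Restrict the metrics table to the strata used for the main contrasts.

    The main land-use and climate contrasts are estimated on the
    temperate/tropical x woodland/agriculture subset (the best-replicated
    strata); other climates and land uses stay in the table until this
    step.
    """
    out = table[
        table["climate_zone"].isin(set(climates)) & table["land_use"].isin(set(land_uses))
    ].reset_index(drop=True)
    if table.shape[0] and out.empty:
        warnings.warn("subset_for_contrasts produced an empty table", stacklevel=2)
    counts = out.groupby(["climate_zone", "land_use"], observed=True).size()
    logger.info("subset_for_contrasts retained %d/%d rows: %s", len(out), len(table),
                counts.to_dict())
    return out


def decomposition_table(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Analysis-ready table for the expansion/partitioning relationship models.

    Pairs natural-log group SEAc with the expansion indicator
    (mean_taxon_seac) and the partitioning indicator (dissimilarity).
    Rows with group_seac == 0 cannot be log-transformed and are excluded
    with a warning; rows missing an indicator appear only in the
    relation that has it.
    """
    counts = {"n_input": int(len(table))}
    tab = table.copy()
    zero = ~(tab["group_seac"] > 0)
    counts["n_zero_seac"] = int(zero.sum())
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} rows with zero/degenerate group SEAc excluded "
            "from log-scale decomposition",
            stacklevel=2,
        )
    tab = tab[~zero].copy()
    tab["log_group_seac"] = np.log(tab["group_seac"])
    counts["n_expansion"] = int(tab["mean_taxon_seac"].notna().sum())
    counts["n_partitioning"] = int(tab["dissimilarity"].notna().sum())
    keep = [
        "site_id", "climate_zone", "land_use", "functional_group",
        "log_group_seac", "mean_taxon_seac", "dissimilarity",
    ]
    return tab[keep].reset_index(drop=True), counts
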