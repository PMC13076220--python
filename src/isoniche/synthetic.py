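"""Synthetic multi-site isotope communities with known ground truth.

The generator emulates the statistical structure the niche analysis
assumes: sites stratified by climate zone x land use; within each site,
several taxa per functional group; per taxon, bivariate-normal isotope
samples around a taxon centroid.  Two knobs control the two routes to
group-level trophic diversity:

* within-taxon covariance ``Sigma_w`` — niche *expansion*;
* isotropic dispersion ``tau`` of taxon centroids around the group
  centroid — niche *partitioning*.

Treatment effects are multiplicative factors ``alpha`` on ``Sigma_w``
and/or ``tau^2`` per stratum; because SEA = pi*sqrt(det(Sigma)) for a
2x2 covariance, multiplying the full covariance by ``alpha`` multiplies
the expected ellipse area by exactly ``alpha``, so a land-use area
multiplier alpha corresponds to a log-scale contrast of ln(alpha).  A
site-level random effect enters as a per-site covariance multiplier
``exp(b_i)``, b_i ~ N(0, site_sd^2), i.e. additively on the log-area
scale — matching the mixed model fitted downstream.

Pooling a group's samples over taxa gives total covariance
``tau^2 * I + Sigma_w`` (law of total variance), so the expected group
ellipse area is available in closed form for recovery tests.

Draw order is fixed (strata in config order; sites, then groups in
sorted name order, then taxa) from a single seeded generator, so a given
(config, seed) pair is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CLIMATE_ZONES, DEFAULT_GROUP_MAP, LAND_USES, FunctionalGroupMap

__all__ = [
    "GroupConfig",
    "Stratum",
    "CommunityConfig",
    "generate_records",
    "expected_group_sea",
    "scenario_library",
]

# Typical soil food-web positions (d13C, d15N) in per mil: detritivores
# near litter, microbivores enriched in 15N, predators at the top.
_DEFAULT_CENTROIDS = {
    "herbivore": (-28.0, 0.5),
    "detritivore": (-26.5, 2.0),
    "microbivore": (-24.5, 4.5),
    "predator": (-23.5, 7.5),
    "mixed": (-25.0, 5.0),
}


@dataclass(frozen=True)
class GroupConfig:
    """Per-functional-group generator settings.

    taxa_count taxa are placed at centroids drawn from
    N(base_centroid, tau^2 I); each taxon contributes samples_per_taxon
    draws (an int, or an inclusive (lo, hi) range sampled per taxon)
    from N(centroid, Sigma_w).
    """

    taxa_count: int = 4
    samples_per_taxon: int | tuple[int, int] = 10
    base_centroid: tuple[float, float] = (-25.0, 4.0)
    within_cov: tuple[tuple[float, float], tuple[float, float]] = ((1.5, 0.2), (0.2, 1.0))
    centroid_sd: float = 1.5  # tau, per mil

    def validate(self) -> None:
        if self.taxa_count < 1:
            raise ValueError("taxa_count must be >= 1")
        spt = self.samples_per_taxon
        if isinstance(spt, tuple):
            if spt[0] < 1 or spt[1] < spt[0]:
                raise ValueError(f"invalid samples_per_taxon range {spt}")
        elif spt < 1:
            raise ValueError("samples_per_taxon must be >= 1")
        cov = np.asarray(self.within_cov, dtype=float)
        if cov.shape != (2, 2) or abs(cov[0, 1] - cov[1, 0]) > 1e-12:
            raise ValueError("within_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("within_cov must be positive semi-definite")
        if self.centroid_sd < 0:
            raise ValueError("centroid_sd must be >= 0")


@dataclass(frozen=True)
class Stratum:
    """One climate-zone x land-use cell with its site count."""

    climate_zone: str
    land_use: str
    n_sites: int
    taxa_count_override: dict | None = None  # group -> taxa_count

    def validate(self) -> None:
        if self.climate_zone not in CLIMATE_ZONES:
            raise ValueError(f"unknown climate_zone {self.climate_zone!r}")
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land_use {self.land_use!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass(frozen=True)
class CommunityConfig:
    """Full parameterization of the synthetic community generator.

    effect_target chooses where the multiplicative stratum factors act:
    "expansion" scales Sigma_w only, "partitioning" scales tau^2 only,
    "both" scales the full group covariance (area multiplier = alpha).
    expansion_site_sd / partitioning_site_sd add independent per-site
    log-normal variation to Sigma_w and tau^2 (used to create gradients
    for the decomposition relationship models); site_sd is the shared
    site random effect on the log-area scale.
    """

    strata: tuple[Stratum, ...] = (
        Stratum("temperate", "woodland", 30),
        Stratum("temperate", "agriculture", 30),
        Stratum("tropical", "woodland", 30),
        Stratum("tropical", "agriculture", 30),
    )
    groups: dict = field(
        default_factory=lambda: {
            "detritivore": GroupConfig(base_centroid=_DEFAULT_CENTROIDS["detritivore"]),
            "microbivore": GroupConfig(
                base_centroid=_DEFAULT_CENTROIDS["microbivore"], taxa_count=5
            ),
            "predator": GroupConfig(base_centroid=_DEFAULT_CENTROIDS["predator"]),
            "herbivore": GroupConfig(
                base_centroid=_DEFAULT_CENTROIDS["herbivore"], taxa_count=3
            ),
        }
    )
    landuse_alpha: dict = field(default_factory=dict)  # land_use -> alpha (>0)
    climate_alpha: dict = field(default_factory=dict)  # climate_zone -> alpha (>0)
    effect_target: str = "both"
    site_sd: float = 0.3
    expansion_site_sd: float = 0.0
    partitioning_site_sd: float = 0.0
    fixed_taxon_centroids: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum required")
        for s in self.strata:
            s.validate()
        for g, gc in self.groups.items():
            if g not in DEFAULT_GROUP_MAP.values():
                raise ValueError(f"unknown functional group {g!r}")
            gc.validate()
        for alpha in list(self.landuse_alpha.values()) + list(self.climate_alpha.values()):
            if not alpha > 0:
                raise ValueError("effect multipliers must be positive")
        if self.effect_target not in {"expansion", "partitioning", "both"}:
            raise ValueError(f"unknown effect_target {self.effect_target!r}")
        if min(self.site_sd, self.expansion_site_sd, self.partitioning_site_sd) < 0:
            raise ValueError("site-level SDs must be >= 0")

    def stratum_alpha(self, stratum: Stratum) -> float:
        return self.landuse_alpha.get(stratum.land_use, 1.0) * self.climate_alpha.get(
            stratum.climate_zone, 1.0
        )


def _effect_covariances(
    config: CommunityConfig, stratum: Stratum, gc: GroupConfig
) -> tuple[np.ndarray, float]:
    """(Sigma_w, tau^2) for a stratum after applying its multipliers."""
    alpha = config.stratum_alpha(stratum)
    sigma_w = np.asarray(gc.within_cov, dtype=float)
    tau2 = gc.centroid_sd**2
    if config.effect_target in {"expansion", "both"}:
        sigma_w = alpha * sigma_w
    if config.effect_target in {"partitioning", "both"}:
        tau2 = alpha * tau2
    return sigma_w, tau2


def expected_group_sea(config: CommunityConfig, stratum: Stratum, group: str) -> float:
    """Closed-form expected group ellipse area pi*sqrt(det(tau^2 I + Sigma_w))."""
    config.validate()
    sigma_w, tau2 = _effect_covariances(config, stratum, config.groups[group])
    total = tau2 * np.eye(2) + sigma_w
    return float(np.pi * np.sqrt(np.linalg.det(total)))


def _taxon_names(group: str, count: int) -> list[str]:
    """Real high-rank taxon names for a group, so group mapping is exercised."""
    pool = sorted(t for t, g in DEFAULT_GROUP_MAP.items() if g == group)
    if count <= len(pool):
        return pool[:count]
    # more taxa than real names: recycle with a numeric suffix (these need a
    # group-map extension at read time, flagged by the caller)
    names = list(pool)
    i = 0
    while len(names) < count:
        names.append(f"{pool[i % len(pool)]}_{i // len(pool) + 2}")
        i += 1
    return names[:count]


def generate_records(
    config: CommunityConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a record table and its ground truth.

    Returns
    -------
    records : DataFrame
        Canonical isotope-record columns (incl. functional_group, family/
        genus/species filled with per-taxon pseudo-ranks so the pipeline's
        resolution levels are exercised).
    truth : DataFrame
        One row per site x group with the realized total covariance
        ``exp(b_site) * (tau^2 I + Sigma_w)`` (after stratum multipliers)
        and its ellipse area, plus the stratum's ln(alpha).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    site_idx = 0
    for stratum in config.strata:
        alpha = config.stratum_alpha(stratum)
        for _ in range(stratum.n_sites):
            site_id = f"site{site_idx:04d}"
            site_idx += 1
            b_site = rng.normal(0.0, config.site_sd) if config.site_sd > 0 else 0.0
            site_mult = float(np.exp(b_site))
            b_exp = rng.normal(0.0, config.expansion_site_sd) if config.expansion_site_sd > 0 else 0.0
            b_part = rng.normal(0.0, config.partitioning_site_sd) if config.partitioning_site_sd > 0 else 0.0
            for group in sorted(config.groups):
                gc = config.groups[group]
                taxa_count = gc.taxa_count
                if stratum.taxa_count_override and group in stratum.taxa_count_override:
                    taxa_count = int(stratum.taxa_count_override[group])
                sigma_w, tau2 = _effect_covariances(config, stratum, gc)
                sigma_w = site_mult * np.exp(b_exp) * sigma_w
                tau2 = site_mult * np.exp(b_part) * tau2
                names = _taxon_names(group, taxa_count)
                if config.fixed_taxon_centroids:
                    # deterministic, variance-matched placement: points evenly
                    # on a circle of radius r have covariance (r^2/2) I, so
                    # r = tau*sqrt(2) reproduces the tau^2 dispersion without
                    # site-to-site sampling variation in realized partitioning
                    angles = 2 * np.pi * np.arange(taxa_count) / max(taxa_count, 1)
                    r = np.sqrt(2.0 * tau2)
                    centroids = np.asarray(gc.base_centroid) + r * np.column_stack(
                        [np.cos(angles), np.sin(angles)]
                    )
                else:
                    centroids = rng.multivariate_normal(
                        gc.base_centroid, tau2 * np.eye(2), size=taxa_count
                    )
                for taxon, centroid in zip(names, centroids):
                    spt = gc.samples_per_taxon
                    n = int(rng.integers(spt[0], spt[1] + 1)) if isinstance(spt, tuple) else spt
                    pts = rng.multivariate_normal(centroid, sigma_w, size=n)
                    for j, (x, y) in enumerate(pts):
                        rec_rows.append(
                            dict(
                                record_id=f"{site_id}-{taxon}-{j:03d}",
                                site_id=site_id,
                                climate_zone=stratum.climate_zone,
                                land_use=stratum.land_use,
                                taxon=taxon,
                                family=f"{taxon}idae",
                                genus=f"{taxon}us",
                                species=f"{taxon}us communis",
                                d13C=float(x),
                                d15N=float(y),
                                functional_group=group,
                            )
                        )
                total = tau2 * np.eye(2) + sigma_w
                truth_rows.append(
                    dict(
                        site_id=site_id,
                        climate_zone=stratum.climate_zone,
                        land_use=stratum.land_use,
                        functional_group=group,
                        var13C=total[0, 0],
                        var15N=total[1, 1],
                        cov=total[0, 1],
                        true_sea=float(np.pi * np.sqrt(np.linalg.det(total))),
                        site_effect=b_site,
                        log_alpha=float(np.log(alpha)),
                    )
                )
    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


def group_map_for(config: CommunityConfig) -> FunctionalGroupMap:
    """Group map covering every taxon name the generator can emit for config.

    Identical to the default map unless a group's taxa_count exceeds its
    real taxon pool, in which case the recycled suffixed names are added.
    """
    entries = dict(DEFAULT_GROUP_MAP)
    counts: dict[str, int] = {g: gc.taxa_count for g, gc in config.groups.items()}
    for s in config.strata:
        for g, c in (s.taxa_count_override or {}).items():
            counts[g] = max(counts.get(g, 0), int(c))
    for g, c in counts.items():
        for name in _taxon_names(g, c):
            entries.setdefault(name, g)
    return FunctionalGroupMap(entries)


def scenario_library() -> dict[str, CommunityConfig]:
    """Named generator presets used by tests and examples.

    * "null" — no treatment effects anywhere.
    * "landuse_expansion" — agriculture inflates within-taxon covariance
      (alpha on Sigma_w only).
    * "landuse_partitioning" — agriculture inflates between-taxon
      centroid dispersion (alpha on tau^2 only).
    * "climate_both" — tropical sites inflate the full group covariance.
    * "decomposition_gradient" — Sigma_w and tau^2 vary independently
      across sites, for the expansion/partitioning relationship models.
    * "richness_gradient" — taxa counts differ between strata.
    """
    two_strata = (
        Stratum("temperate", "woodland", 40),
        Stratum("temperate", "agriculture", 40),
    )
    return {
        "null": CommunityConfig(),
        "landuse_expansion": CommunityConfig(
            strata=two_strata,
            landuse_alpha={"agriculture": 1.6},
            effect_target="expansion",
        ),
        "landuse_partitioning": CommunityConfig(
            strata=two_strata,
            landuse_alpha={"agriculture": 1.6},
            effect_target="partitioning",
        ),
        "climate_both": CommunityConfig(
            strata=(
                Stratum("temperate", "woodland", 40),
                Stratum("tropical", "woodland", 40),
            ),
            climate_alpha={"tropical": 1.4},
            effect_target="both",
        ),
        "decomposition_gradient": CommunityConfig(
            strata=(Stratum("temperate", "woodland", 60),),
            expansion_site_sd=0.5,
            partitioning_site_sd=0.5,
        ),
        "richness_gradient": CommunityConfig(
            strata=(
                Stratum("temperate", "woodland", 40),
                Stratum(
                    "temperate",
                    "agriculture",
                    40,
                    taxa_count_override={"microbivore": 7, "detritivore": 6},
                ),
            ),
        ),
    }
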