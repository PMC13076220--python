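"""Simulation experiments that validate the pipeline against known truth.

Each function runs the package end to end on generator output (or on
direct Monte-Carlo draws for the geometry checks) and returns measured
quantities: ellipse coverage, SEAc bias, recovery of multiplicative
land-use effects, discrimination of niche expansion from partitioning,
and the calibration/power of the Moran's I diagnostic.  They are used
by the test suite and by the reproduction script; all take an explicit
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effect_models
from .niche_metrics import points_inside_ellipse
from .pipeline import compute_site_metrics
from .synthetic import CommunityConfig, GroupConfig, Stratum, generate_records

__all__ = [
    "ellipse_coverage_fraction",
    "seac_bias_experiment",
    "recovery_config",
    "landuse_contrast_replicates",
    "discrimination_replicates",
    "moran_null_rejection_rate",
    "moran_power",
]


def ellipse_coverage_fraction(
    n_draws: int = 100_000,
    cov=((2.0, 0.7), (0.7, 1.2)),
    seed: int = 0,
) -> float:
    """Fraction of bivariate-normal draws inside the true 1-SD ellipse.

    The analytic value is P(chi2_2 <= 1) = 1 - exp(-1/2) ~ 0.3935.
    """
    rng = np.random.default_rng(seed)
    cov = np.asarray(cov, dtype=float)
    mu = np.array([-25.0, 4.0])
    pts = rng.multivariate_normal(mu, cov, size=n_draws)
    return float(points_inside_ellipse(pts, mu, cov).mean())


def seac_bias_experiment(
    n: int = 5,
    n_reps: int = 5000,
    cov=((1.8, 0.4), (0.4, 1.1)),
    seed: int = 0,
) -> dict[str, float]:
    """Mean SEA and SEAc over replicate small samples vs the true area.

    SEA underestimates the population ellipse area by a factor
    (n-2)/(n-1); the SEAc correction removes that bias, which is the
    point of using it at small, variable sample sizes.
    """
    rng = np.random.default_rng(seed)
    cov = np.asarray(cov, dtype=float)
    true_area = float(np.pi * np.sqrt(np.linalg.det(cov)))
    draws = rng.multivariate_normal(np.zeros(2), cov, size=(n_reps, n))
    centered = draws - draws.mean(axis=1, keepdims=True)
    s = np.einsum("rni,rnj->rij", centered, centered) / (n - 1)
    det = s[:, 0, 0] * s[:, 1, 1] - s[:, 0, 1] ** 2
    sea = np.pi * np.sqrt(np.clip(det, 0.0, None))
    return {
        "true_area": true_area,
        "mean_sea": float(sea.mean()),
        "mean_seac": float(sea.mean() * (n - 1) / (n - 2)),
        "n": n,
        "n_reps": n_reps,
    }


def recovery_config(alpha: float, n_sites: int = 100, seed: int = 0) -> CommunityConfig:
    """Woodland-vs-agriculture design with area multiplier alpha on agriculture.

    Two functional groups per site keep the site random intercept
    identifiable; the multiplier acts on the full group covariance, so
    the true log-scale land-use contrast is exactly ln(alpha).
    """
    return CommunityConfig(
        strata=(
            Stratum("temperate", "woodland", n_sites),
            Stratum("temperate", "agriculture", n_sites),
        ),
        groups={
            "microbivore": GroupConfig(base_centroid=(-24.5, 4.5), taxa_count=4),
            "predator": GroupConfig(base_centroid=(-23.5, 7.5), taxa_count=4),
        },
        landuse_alpha={"agriculture": alpha},
        effect_target="both",
        site_sd=0.3,
        seed=seed,
    )


@dataclass
class ContrastReplicates:
    """Per-replicate land-use contrasts from the full pipeline."""

    estimates: np.ndarray
    ses: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    true_log_ratio: float

    @property
    def coverage(self) -> float:
        """Fraction of replicate 95% CIs containing the true log ratio."""
        return float(
            np.mean((self.ci_lo <= self.true_log_ratio) & (self.true_log_ratio <= self.ci_hi))
        )

    @property
    def mean_percent(self) -> float:
        return float((np.exp(self.estimates.mean()) - 1.0) * 100.0)


def _one_landuse_contrast(
    config: CommunityConfig,
    seed: int,
    response: str = "log_group_seac",
) -> effect_models.EffectEstimate:
    records, _ = generate_records(config, seed=seed)
    table, _ = compute_site_metrics(records)
    fit = effect_models.fit_lmm(
        table, response=response, factors=("functional_group", "land_use")
    )
    return effect_models.emm_contrast(fit, "land_use", pair=("agriculture", "woodland"))[0]


def landuse_contrast_replicates(
    alpha: float,
    n_reps: int = 100,
    n_sites: int = 100,
    seed: int = 0,
) -> ContrastReplicates:
    """Replicate the full simulate -> metrics -> LMM -> contrast chain.

    Returns the per-replicate log-scale agriculture-woodland contrasts
    and their CIs; ``coverage`` measures how often the 95% CI contains
    the generator's true ln(alpha).
    """
    config = recovery_config(alpha, n_sites=n_sites)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    est, ses, lo, hi = [], [], [], []
    for s in sub_seeds:
        e = _one_landuse_contrast(config, seed=int(s))
        est.append(e.estimate)
        ses.append(e.se)
        lo.append(e.ci95[0])
        hi.append(e.ci95[1])
    return ContrastReplicates(
        estimates=np.array(est),
        ses=np.array(ses),
        ci_lo=np.array(lo),
        ci_hi=np.array(hi),
        true_log_ratio=float(np.log(alpha)),
    )


def discrimination_replicates(
    target: str,
    alpha: float = 1.6,
    n_reps: int = 40,
    n_sites: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Expansion-vs-partitioning discrimination on generator ground truth.

    ``target`` is "expansion" (alpha on the within-taxon covariance) or
    "partitioning" (alpha on the centroid dispersion).  For each
    replicate the land-use contrast is estimated for both indicators —
    log mean taxon SEAc and log between-taxon dissimilarity — and the
    replicate is scored correct when the targeted indicator's contrast
    is positive with a 95% CI excluding 0 and has the larger
    standardized effect of the two.
    """
    config = CommunityConfig(
        strata=(
            Stratum("temperate", "woodland", n_sites),
            Stratum("temperate", "agriculture", n_sites),
        ),
        groups={
            "microbivore": GroupConfig(base_centroid=(-24.5, 4.5), taxa_count=4),
            "predator": GroupConfig(base_centroid=(-23.5, 7.5), taxa_count=4),
        },
        landuse_alpha={"agriculture": alpha},
        effect_target=target,
        site_sd=0.3,
    )
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    rows = []
    for s in sub_seeds:
        records, _ = generate_records(config, seed=int(s))
        table, _ = compute_site_metrics(records)
        res = {}
        for name, response in [
            ("expansion", "log_mean_taxon_seac"),
            ("partitioning", "log_dissimilarity"),
        ]:
            fit = effect_models.fit_lmm(
                table, response=response, factors=("functional_group", "land_use")
            )
            res[name] = effect_models.emm_contrast(
                fit, "land_use", pair=("agriculture", "woodland")
            )[0]
        tgt, other = res[target], res["expansion" if target == "partitioning" else "partitioning"]
        rows.append(
            dict(
                target_estimate=tgt.estimate,
                target_ci_lo=tgt.ci95[0],
                target_ci_hi=tgt.ci95[1],
                other_estimate=other.estimate,
                other_se=other.se,
                correct=(
                    tgt.estimate > 0
                    and tgt.ci95[0] > 0
                    and abs(tgt.estimate / tgt.se) > abs(other.estimate / other.se)
                ),
                target_se=tgt.se,
            )
        )
    return pd.DataFrame(rows)


def _random_sites(n_sites: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    lon = rng.uniform(-10.0, 30.0, size=n_sites)
    lat = rng.uniform(35.0, 60.0, size=n_sites)
    return lon, lat


def moran_null_rejection_rate(
    n_reps: int = 1000,
    n_sites: int = 100,
    k: int = 5,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Rejection rate of the permutation Moran's I test on iid residuals.

    Should sit at the nominal 5% level; site coordinates are fixed
    across replicates, residuals redrawn.
    """
    rng = np.random.default_rng(seed)
    lon, lat = _random_sites(n_sites, rng)
    w = effect_models.knn_weights(lon, lat, k=k)
    rejections = 0
    for _ in range(n_reps):
        z = rng.normal(size=n_sites)
        res = effect_models.moran_i(
            z, lon, lat, k=k, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), weights=w
        )
        rejections += res.p_value <= 0.05
    return rejections / n_reps


def moran_power(
    n_reps: int = 200,
    n_sites: int = 100,
    k: int = 5,
    n_perm: int = 999,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> float:
    """Power against a smooth latitudinal gradient in the residuals."""
    rng = np.random.default_rng(seed)
    lon, lat = _random_sites(n_sites, rng)
    w = effect_models.knn_weights(lon, lat, k=k)
    gradient = (lat - lat.mean()) / lat.std()
    rejections = 0
    for _ in range(n_reps):
        z = gradient + rng.normal(scale=noise_sd, size=n_sites)
        res = effect_models.moran_i(
            z, lon, lat, k=k, n_perm=n_perm, seed=int(rng.integers(2**31 - 1)), weights=w
        )
        rejections += (res.p_value <= 0.05) and (res.i > 0)
    return rejections / n_reps
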