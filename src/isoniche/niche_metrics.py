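"""Core isotopic-niche statistics on the δ13C–δ15N biplot.

Trophic niche breadth is measured as the standard ellipse area (SEA):
the area of the 1-standard-deviation ellipse of a bivariate point cloud,

    SEA = pi * sqrt(det(Sigma)),

where Sigma is the sample covariance of (δ13C, δ15N).  For a bivariate
normal this ellipse covers 1 - exp(-1/2) ≈ 39.35% of the distribution.
Because SEA is biased low at small n, the small-sample corrected area

    SEAc = SEA * (n - 1) / (n - 2)

is used throughout.  Niche partitioning between taxa is measured as the
mean pairwise Euclidean distance between taxon centroids in isotope
space (per mil units on unscaled axes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EllipseFit",
    "InsufficientSampleError",
    "InvalidCovarianceError",
    "fit_centroid_covariance",
    "standard_ellipse_area",
    "seac",
    "fit_ellipse",
    "isotope_sds",
    "min_sample_filter",
    "trophic_dissimilarity",
    "points_inside_ellipse",
]

_PSD_TOL = 1e-10


class InsufficientSampleError(ValueError):
    """Too few points for the requested statistic."""


class InvalidCovarianceError(ValueError):
    """Covariance matrix is not symmetric positive semi-definite."""


@dataclass(frozen=True)
class EllipseFit:
    """Standard-ellipse fit for one group at one site.

    Attributes
    ----------
    centroid : (2,) ndarray
        Mean (δ13C, δ15N) in per mil.
    covariance : (2, 2) ndarray
        Sample covariance (n-1 denominator), per mil squared.
    n : int
        Number of samples.
    sea : float
        Standard ellipse area, per mil squared.
    seac : float
        Small-sample corrected area, per mil squared.
    """

    centroid: np.ndarray
    covariance: np.ndarray
    n: int
    sea: float
    seac: float


def _as_points(points: Iterable) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of (d13C, d15N) points, got {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite values")
    return pts


def fit_centroid_covariance(points: Iterable) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate-wise mean and sample covariance (n-1 denominator) of a point cloud."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise InsufficientSampleError(f"need >= 2 points, got {len(pts)}")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    cov = 0.5 * (cov + cov.T)  # enforce exact symmetry
    return centroid, cov


def _check_covariance(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise InvalidCovarianceError(f"expected a 2x2 matrix, got {cov.shape}")
    if not np.isfinite(cov).all():
        raise InvalidCovarianceError("covariance contains non-finite values")
    if abs(cov[0, 1] - cov[1, 0]) > _PSD_TOL * max(1.0, np.abs(cov).max()):
        raise InvalidCovarianceError("covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    if eigvals.min() < -_PSD_TOL * max(1.0, eigvals.max(), 0.0):
        raise InvalidCovarianceError(f"covariance is not PSD (eigenvalues {eigvals})")
    return 0.5 * (cov + cov.T)


def standard_ellipse_area(cov: np.ndarray) -> float:
    """Area of the 1-SD ellipse: pi * sqrt(det(Sigma)).

    The ellipse's semi-axes are the square roots of Sigma's eigenvalues,
    so the area is pi times the product of the semi-axes.  Rank-deficient
    covariances (collinear data) give area 0.
    """
    cov = _check_covariance(cov)
    det = float(np.linalg.det(cov))
    return float(np.pi * np.sqrt(max(det, 0.0)))


def seac(sea: float, n: int) -> float:
    """Small-sample corrected ellipse area: SEA * (n-1)/(n-2).

    Undefined for n <= 2; raising (rather than silently returning the
    uncorrected area) keeps the correction explicit.
    """
    if n <= 2:
        raise InsufficientSampleError(f"SEAc undefined for n = {n} (need n >= 3)")
    if sea < 0:
        raise ValueError("SEA must be non-negative")
    return float(sea) * (n - 1) / (n - 2)


def fit_ellipse(points: Iterable) -> EllipseFit:
    """Fit centroid, covariance, SEA and SEAc for one group's point cloud (n >= 3)."""
    pts = _as_points(points)
    if len(pts) < 3:
        raise InsufficientSampleError(f"need >= 3 points for SEAc, got {len(pts)}")
    centroid, cov = fit_centroid_covariance(pts)
    sea = standard_ellipse_area(cov)
    return EllipseFit(centroid=centroid, covariance=cov, n=len(pts), sea=sea,
                      seac=seac(sea, len(pts)))


def isotope_sds(points: Iterable) -> tuple[float, float]:
    """Coordinate-wise sample SDs (n-1 denominator) of δ13C and δ15N.

    Within a functional group at a site these index variation in basal
    resource use (δ13C) and trophic position (δ15N) respectively.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise InsufficientSampleError(f"need >= 2 points, got {len(pts)}")
    sds = pts.std(axis=0, ddof=1)
    return float(sds[0]), float(sds[1])


def min_sample_filter(
    samples: dict, threshold: int = 5
) -> tuple[dict, list[tuple]]:
    """Retain groups with at least ``threshold`` samples.

    Parameters
    ----------
    samples : dict
        Mapping from a group key (e.g. ``(site_id, group)``) to its point
        array.
    threshold : int
        Minimum sample count; must be >= 3 because SEAc is undefined
        below 3.

    Returns
    -------
    retained : dict
        The qualifying subset, same keys.
    excluded : list of (key, n)
        Exclusion report for the groups that failed the filter.
    """
    if threshold < 3:
        raise ValueError(f"threshold must be >= 3 (SEAc undefined below 3), got {threshold}")
    retained, excluded = {}, []
    for key, pts in samples.items():
        n = len(np.asarray(pts))
        if n >= threshold:
            retained[key] = pts
        else:
            excluded.append((key, n))
    return retained, excluded


def trophic_dissimilarity(centroids: Sequence) -> float:
    """Mean pairwise Euclidean distance between taxon centroids (per mil).

    The niche-partitioning indicator: the arithmetic mean of distances
    over all unordered centroid pairs.  Undefined (NaN, never 0) for
    fewer than two centroids.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (m, 2) array of centroids, got {pts.shape}")
    if len(pts) < 2:
        return float("nan")
    diff = pts[:, None, :] - pts[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(len(pts), k=1)
    return float(dists[iu].mean())


def points_inside_ellipse(points: Iterable, centroid, cov) -> np.ndarray:
    """Boolean mask of points inside the 1-SD ellipse of (centroid, cov).

    A point z is inside when (z - mu)^T Sigma^{-1} (z - mu) <= 1.
    """
    pts = _as_points(points)
    mu = np.asarray(centroid, dtype=float)
    cov = _check_covariance(cov)
    diff = pts - mu
    sol = np.linalg.solve(cov, diff.T).T
    return (diff * sol).sum(axis=1) <= 1.0
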