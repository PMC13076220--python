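"""Mixed-model layer: land-use and climate effects on log niche metrics.

Log-transformed SEAc (or dissimilarity) is modelled with linear mixed
models: functional group, land use, climate zone and their interactions
as fixed effects and a site random intercept (multiple functional-group
rows from one site are not independent).  Effects are reported as
estimated-marginal-mean contrasts: model predictions averaged over a
balanced grid of the remaining factors (equal weight per cell), with
contrasts formed on the log scale and back-transformed to percent
differences, (e^est - 1) * 100 — the multiplicative reading of a
log-response ratio.  Spatial autocorrelation of site-level residuals is
checked with Moran's I on k-nearest-neighbour weights with a
permutation null.

REML fitting is delegated to statsmodels' MixedLM; the marginal-mean
grid, contrast algebra, delta-method back-transform and Moran's I are
implemented here.  Confidence intervals use the normal approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "LmmFit",
    "EffectEstimate",
    "MoranResult",
    "SingularDesignError",
    "fit_lmm",
    "emm_contrast",
    "covariate_model",
    "decomposition_models",
    "moran_i",
]

Z95 = float(stats.norm.ppf(0.975))


class SingularDesignError(ValueError):
    """Fixed-effect design matrix is rank deficient (aliased terms)."""


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


@dataclass
class EffectEstimate:
    """A log-scale contrast with its back-transformed percent effect.

    ``estimate`` is the log-response ratio (difference of log-scale
    marginal means), ``percent`` = (e^estimate - 1) * 100, and
    ``percent_se`` its delta-method standard error e^estimate * se * 100.
    """

    label: str
    estimate: float
    se: float
    ci95: tuple[float, float]
    percent: float
    percent_se: float
    percent_ci95: tuple[float, float]

    @classmethod
    def from_log_scale(cls, label: str, est: float, se: float) -> "EffectEstimate":
        lo, hi = est - Z95 * se, est + Z95 * se
        return cls(
            label=label,
            estimate=est,
            se=se,
            ci95=(lo, hi),
            percent=(np.exp(est) - 1.0) * 100.0,
            percent_se=np.exp(est) * se * 100.0,
            percent_ci95=((np.exp(lo) - 1.0) * 100.0, (np.exp(hi) - 1.0) * 100.0),
        )


@dataclass
class LmmFit:
    """A fitted mixed model plus the metadata the contrast layer needs."""

    result: object  # MixedLMResults
    formula: str
    factors: list[str]
    covariates: list[str]
    response: str
    data: pd.DataFrame
    n_dropped: int
    dropped_factors: list[str] = field(default_factory=list)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def cov_fe(self) -> np.ndarray:
        k = len(self.result.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    @property
    def site_sd(self) -> float:
        """Estimated SD of the site random intercept (response-scale units)."""
        return float(np.sqrt(self.result.cov_re.iloc[0, 0]))

    @property
    def residual_sd(self) -> float:
        return float(np.sqrt(self.result.scale))

    def site_residuals(self) -> pd.DataFrame:
        """Mean marginal residual per site (for spatial diagnostics)."""
        res = pd.DataFrame(
            {"site_id": self.data["site_id"].to_numpy(), "resid": np.asarray(self.result.resid)}
        )
        return res.groupby("site_id", observed=True)["resid"].mean().reset_index()

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_fe))
        return pd.DataFrame(
            {"estimate": self.fe_params.to_numpy(), "se": se},
            index=self.fe_params.index,
        )


def _fit_reml(model, reml: bool = True):
    """REML fit with the default optimizer, falling back to Powell."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = model.fit(reml=reml)
            if result.converged:
                return result
        except np.linalg.LinAlgError:
            pass
        return model.fit(reml=reml, method="powell")


def _check_design(df: pd.DataFrame, formula: str) -> None:
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal does not drop the rank
        aliased = []
        arr = X.to_numpy()
        for j, name in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(name)
        raise SingularDesignError(f"design matrix is rank deficient; aliased terms: {aliased}")


def fit_lmm(
    table: pd.DataFrame,
    response: str = "log_group_seac",
    factors: tuple[str, ...] = ("functional_group", "land_use", "climate_zone"),
    covariates: tuple[str, ...] = (),
    interactions: bool = True,
    random_taxon: str | None = None,
    reml: bool = True,
) -> LmmFit:
    """Fit a site-random-intercept LMM for a log-scale niche metric.

    ``response`` may name an existing column or a metric column to be
    natural-log transformed on the fly (``log_<metric>``).  Factors with
    fewer than two observed levels are dropped (with a warning) rather
    than erroring, since stratified subsets routinely fix a factor.
    ``random_taxon`` optionally names a column to add as a
    taxon-identity variance component (modelled within site, the closest
    structure statsmodels supports).

    With no between-site variance in the data the site variance
    component collapses to ~0 and the fixed effects coincide with OLS.
    """
    df = table.copy()
    if response not in df.columns and response.startswith("log_"):
        base = response[4:]
        if base not in df.columns:
            raise KeyError(f"no column {base!r} to log-transform for response {response!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            df[response] = np.log(df[base].where(df[base] > 0))

    finite = np.ones(len(df), dtype=bool)
    for c in [response, *covariates]:
        finite &= np.isfinite(pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float))
    n_dropped = int((~finite).sum())
    df = df[finite].copy()
    if df.empty:
        raise ValueError("no rows with finite response/covariates")

    kept_factors, dropped = [], []
    for f in factors:
        if df[f].nunique() >= 2:
            kept_factors.append(f)
        else:
            dropped.append(f)
    if dropped:
        warnings.warn(f"factors with < 2 observed levels dropped: {dropped}", stacklevel=2)

    for c in covariates:
        if df[c].nunique() < 2:
            raise SingularDesignError(f"covariate {c!r} is constant (aliased with intercept)")

    if kept_factors:
        joiner = " * " if interactions and len(kept_factors) > 1 else " + "
        fixed = joiner.join(f"C({f})" for f in kept_factors)
    else:
        fixed = "1"
    if covariates:
        fixed = fixed + " + " + " + ".join(covariates)
    formula = f"{response} ~ {fixed}"
    _check_design(df, formula)

    if df["site_id"].nunique() < 2:
        raise ValueError("need >= 2 sites for a site random intercept")

    vc = {"taxon": f"0 + C({random_taxon})"} if random_taxon else None
    model = smf.mixedlm(formula, df, groups=df["site_id"], vc_formula=vc)
    result = _fit_reml(model, reml)
    if not result.converged:
        raise ConvergenceError(
            f"REML did not converge for {formula!r} "
            f"(n={len(df)}, sites={df['site_id'].nunique()})"
        )
    return LmmFit(
        result=result,
        formula=formula,
        factors=kept_factors,
        covariates=list(covariates),
        response=response,
        data=df,
        n_dropped=n_dropped,
        dropped_factors=dropped,
    )


def _balanced_grid(fit: LmmFit) -> pd.DataFrame:
    levels = {f: sorted(fit.data[f].unique()) for f in fit.factors}
    combos = list(itertools.product(*levels.values()))
    grid = pd.DataFrame(combos, columns=list(levels))
    for c in fit.covariates:  # covariates held at their observed mean
        grid[c] = float(pd.to_numeric(fit.data[c]).mean())
    return grid


def _design_rows(fit: LmmFit, grid: pd.DataFrame) -> np.ndarray:
    design_info = fit.result.model.data.design_info
    (X,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(X)


def emm_contrast(
    fit: LmmFit,
    factor: str,
    pair: tuple[str, str] | None = None,
    by: str | None = None,
) -> list[EffectEstimate]:
    """Estimated-marginal-mean contrast(s) for one factor.

    Marginal means are model predictions averaged over a balanced grid
    of the other factors (equal weight per cell, the emmeans default).
    ``pair=(a, b)`` contrasts level a minus level b (default: last level
    minus first alphabetically); ``by`` computes the contrast separately
    within each level of another factor.
    """
    if factor not in fit.factors:
        raise ValueError(f"factor {factor!r} not in the fitted model ({fit.factors})")
    if by is not None and by not in fit.factors:
        raise ValueError(f"'by' factor {by!r} not in the fitted model")
    levels = sorted(fit.data[factor].unique())
    if pair is None:
        pair = (levels[-1], levels[0])
    a, b = pair
    for lev in pair:
        if lev not in levels:
            raise ValueError(f"level {lev!r} not observed for factor {factor!r}")

    grid = _balanced_grid(fit)
    X = _design_rows(fit, grid)
    beta = fit.fe_params.to_numpy()
    cov = fit.cov_fe

    by_levels = sorted(fit.data[by].unique()) if by else [None]
    out = []
    for bl in by_levels:
        mask_extra = np.ones(len(grid), dtype=bool) if bl is None else (grid[by] == bl).to_numpy()
        la = ((grid[factor] == a).to_numpy() & mask_extra)
        lb = ((grid[factor] == b).to_numpy() & mask_extra)
        L = X[la].mean(axis=0) - X[lb].mean(axis=0)
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        label = f"{a} - {b}" if bl is None else f"{a} - {b} | {by}={bl}"
        out.append(EffectEstimate.from_log_scale(label, est, se))
    return out


def emm_means(fit: LmmFit, factor: str) -> pd.DataFrame:
    """Balanced-grid marginal means (log scale) for each level of a factor."""
    grid = _balanced_grid(fit)
    X = _design_rows(fit, grid)
    beta, cov = fit.fe_params.to_numpy(), fit.cov_fe
    rows = []
    for lev in sorted(fit.data[factor].unique()):
        L = X[(grid[factor] == lev).to_numpy()].mean(axis=0)
        est, se = float(L @ beta), float(np.sqrt(L @ cov @ L))
        rows.append(dict(level=lev, emmean=est, se=se,
                         ci_lo=est - Z95 * se, ci_hi=est + Z95 * se))
    return pd.DataFrame(rows)


def covariate_model(
    table: pd.DataFrame,
    response: str = "log_group_seac",
    covariates: tuple[str, ...] = ("sampling_number", "family_richness"),
    factors: tuple[str, ...] = ("functional_group", "land_use", "climate_zone"),
) -> LmmFit:
    """Covariate-adjusted LMM: factors plus sampling effort and richness.

    Fixed effects are additive here (no interactions), mirroring the
    covariate-adjustment model that asks whether land-use and climate
    effects persist once sampling number and family richness are
    accounted for.  ``sampling_number`` maps onto the metrics table's
    ``n_samples`` column when not present under its own name.
    """
    table = table.copy()
    if "sampling_number" in covariates and "sampling_number" not in table.columns:
        if "n_samples" in table.columns:
            table["sampling_number"] = table["n_samples"].astype(float)
    return fit_lmm(
        table,
        response=response,
        factors=factors,
        covariates=covariates,
        interactions=False,
    )


@dataclass
class SlopeFit:
    """Slope of log group SEAc on one decomposition indicator."""

    predictor: str
    slope: float
    se: float
    ci95: tuple[float, float]
    r2_marginal: float
    r2_conditional: float
    per_group: pd.DataFrame
    fit: LmmFit


def _nakagawa_r2(fit: LmmFit) -> tuple[float, float]:
    X = np.asarray(patsy.dmatrix(fit.result.model.data.design_info, fit.data))
    var_f = float(np.var(X @ fit.fe_params.to_numpy(), ddof=0))
    var_re = float(fit.result.cov_re.iloc[0, 0])
    var_resid = float(fit.result.scale)
    denom = var_f + var_re + var_resid
    if denom == 0.0:  # constant response: no variance to explain
        return 0.0, 0.0
    return var_f / denom, (var_f + var_re) / denom


def _slope_model(df: pd.DataFrame, predictor: str) -> SlopeFit:
    sub = df[np.isfinite(df[predictor]) & np.isfinite(df["log_group_seac"])]
    formula = f"log_group_seac ~ {predictor}"
    model = smf.mixedlm(formula, sub, groups=sub["site_id"])
    result = _fit_reml(model)
    lf = LmmFit(result=result, formula=formula, factors=[], covariates=[predictor],
                response="log_group_seac", data=sub, n_dropped=len(df) - len(sub))
    est = float(result.fe_params[predictor])
    se = float(np.sqrt(lf.cov_fe[1, 1]))
    r2m, r2c = _nakagawa_r2(lf)
    per_group = []
    for g, gsub in sub.groupby("functional_group", observed=True):
        if gsub[predictor].nunique() < 2 or len(gsub) < 3:
            continue
        sl, icpt, r, p, sl_se = stats.linregress(gsub[predictor], gsub["log_group_seac"])
        per_group.append(dict(functional_group=g, slope=sl, se=sl_se, n=len(gsub)))
    return SlopeFit(
        predictor=predictor,
        slope=est,
        se=se,
        ci95=(est - Z95 * se, est + Z95 * se),
        r2_marginal=r2m,
        r2_conditional=r2c,
        per_group=pd.DataFrame(per_group),
        fit=lf,
    )


def decomposition_models(decomp: pd.DataFrame) -> dict[str, SlopeFit]:
    """Fit the two decomposition relations with site random intercepts.

    ``expansion``: log group SEAc ~ mean taxon SEAc;
    ``partitioning``: log group SEAc ~ between-taxon dissimilarity.
    Pooled slope with CI and marginal/conditional variance explained,
    plus per-functional-group OLS slopes.
    """
    return {
        "expansion": _slope_model(decomp, "mean_taxon_seac"),
        "partitioning": _slope_model(decomp, "dissimilarity"),
    }


@dataclass
class MoranResult:
    """Moran's I with its permutation p-value."""

    i: float
    expected: float
    p_value: float
    n_perm: int
    n_sites: int


def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lam, phi = np.radians(lon), np.radians(lat)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    return 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))  # radians; radius cancels in kNN


def knn_weights(lon, lat, k: int = 5) -> np.ndarray:
    """Row-standardized k-nearest-neighbour weight matrix (great-circle)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    if n < k + 2:
        raise ValueError(f"need at least k+2={k + 2} sites, got {n}")
    d = _haversine_matrix(lon, lat)
    np.fill_diagonal(d, np.inf)
    w = np.zeros((n, n))
    idx = np.argsort(d, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    w[rows, idx.ravel()] = 1.0 / k
    return w


def moran_i(
    residuals,
    lon,
    lat,
    k: int = 5,
    n_perm: int = 999,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> MoranResult:
    """Moran's I of site residuals with a two-sided permutation test.

    I = (n / sum(w)) * sum_ij(w_ij z_i z_j) / sum_i(z_i^2) with
    z = residual - mean and row-standardized k-nearest-neighbour weights
    on great-circle distances.  The null distribution comes from
    ``n_perm`` random permutations of the residuals across sites; the
    p-value is two-sided around the permutation mean E[I] = -1/(n-1).
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant residuals")
    w = knn_weights(lon, lat, k=k) if weights is None else np.asarray(weights, dtype=float)
    s0 = w.sum()
    i_obs = float(n / s0 * (z @ w @ z) / denom)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(z, (n_perm, 1)), axis=1)
    i_perm = n / s0 * ((perms @ w.T) * perms).sum(axis=1) / denom
    e_i = -1.0 / (n - 1)
    extreme = np.abs(i_perm - e_i) >= abs(i_obs - e_i) - 1e-15
    p = (1.0 + int(extreme.sum())) / (n_perm + 1.0)
    return MoranResult(i=i_obs, expected=e_i, p_value=float(p), n_perm=n_perm, n_sites=n)
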