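"""Mixed models, marginal-mean contrasts, decomposition relations, Moran's I."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from isoniche import (
    CommunityConfig,
    GroupConfig,
    Stratum,
    compute_site_metrics,
    covariate_model,
    decomposition_models,
    decomposition_table,
    emm_contrast,
    emm_means,
    fit_lmm,
    generate_records,
    moran_i,
)
from isoniche.effect_models import EffectEstimate, SingularDesignError, knn_weights


def _balanced_table(site_sd: float, seed: int = 0, n_sites: int = 40,
                    effects=(0.0, 0.0), resid_sd: float = 0.2) -> pd.DataFrame:
    """Balanced two-factor log-metric table with a known site effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        lu = "agriculture" if s % 2 else "woodland"
        b = rng.normal(0, site_sd) if site_sd > 0 else 0.0
        for g_idx, g in enumerate(["microbivore", "predator"]):
            y = (
                1.0
                + effects[0] * (lu == "agriculture")
                + effects[1] * g_idx
                + b
                + rng.normal(0, resid_sd)
            )
            rows.append(dict(site_id=f"s{s:03d}", land_use=lu, climate_zone="temperate",
                             functional_group=g, log_group_seac=y))
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_zero_site_variance_matches_ols(self):
        """With no between-site variance the LMM fixed effects are OLS."""
        import statsmodels.formula.api as smf

        table = _balanced_table(site_sd=0.0, effects=(0.3, -0.2))
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        ols = smf.ols(
            "log_group_seac ~ C(functional_group) * C(land_use)", table
        ).fit()
        np.testing.assert_allclose(
            fit.fe_params.to_numpy(), ols.params.to_numpy(), atol=1e-6
        )

    def test_site_sd_recovery(self):
        """Known site SD 0.5 on the log scale, 200 sites: estimate within 0.1."""
        table = _balanced_table(site_sd=0.5, n_sites=200, seed=3)
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        assert fit.site_sd == pytest.approx(0.5, abs=0.1)

    def test_nonfinite_response_rows_dropped_and_counted(self):
        table = _balanced_table(site_sd=0.2)
        table.loc[0, "log_group_seac"] = np.nan
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        assert fit.n_dropped == 1

    def test_log_transform_on_the_fly(self):
        table = _balanced_table(site_sd=0.2)
        table["group_seac"] = np.exp(table["log_group_seac"])
        fit = fit_lmm(table.drop(columns="log_group_seac"),
                      response="log_group_seac",
                      factors=("functional_group", "land_use"))
        assert fit.response == "log_group_seac"

    def test_single_level_factor_dropped_with_warning(self):
        table = _balanced_table(site_sd=0.2)
        with pytest.warns(UserWarning, match="climate_zone"):
            fit = fit_lmm(table)
        assert fit.dropped_factors == ["climate_zone"]

    def test_constant_covariate_is_singular(self):
        table = _balanced_table(site_sd=0.2)
        table["sampling_number"] = 7.0
        with pytest.raises(SingularDesignError, match="sampling_number"):
            fit_lmm(table, factors=("functional_group", "land_use"),
                    covariates=("sampling_number",))

    def test_taxon_variance_component(self):
        table = _balanced_table(site_sd=0.2, n_sites=60)
        table["taxon"] = np.where(table["functional_group"] == "predator",
                                  "Araneae", "Collembola")
        fit = fit_lmm(table, factors=("land_use",), random_taxon="taxon")
        assert fit.result.converged


class TestEmmContrast:
    def test_zero_estimate_zero_percent(self):
        e = EffectEstimate.from_log_scale("x", 0.0, 0.1)
        assert e.percent == 0.0

    def test_back_transform_matches_percent_scale(self):
        e = EffectEstimate.from_log_scale("x", np.log(1.321), 0.05)
        assert e.percent == pytest.approx(32.1, abs=1e-9)
        assert e.percent_se == pytest.approx(1.321 * 0.05 * 100, rel=1e-12)

    def test_ci_brackets_estimate(self):
        e = EffectEstimate.from_log_scale("x", 0.3, 0.1)
        assert e.ci95[0] < e.estimate < e.ci95[1]
        assert e.percent_ci95[0] < e.percent < e.percent_ci95[1]

    def test_balanced_saturated_reduces_to_cell_means(self):
        """On a balanced design the balanced-grid marginal means equal simple
        factor means of the cell means (exact)."""
        table = _balanced_table(site_sd=0.0, effects=(0.4, -0.3), resid_sd=0.1, seed=5)
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        cell = table.groupby(["functional_group", "land_use"])["log_group_seac"].mean()
        expected = cell.groupby("land_use").mean()
        est = emm_contrast(fit, "land_use", pair=("agriculture", "woodland"))[0]
        assert est.estimate == pytest.approx(
            expected["agriculture"] - expected["woodland"], abs=1e-8
        )
        means = emm_means(fit, "land_use")
        for _, row in means.iterrows():
            assert row["emmean"] == pytest.approx(expected[row["level"]], abs=1e-8)

    def test_by_group_contrasts(self):
        table = _balanced_table(site_sd=0.1, effects=(0.4, -0.3), seed=6)
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        ests = emm_contrast(fit, "land_use", pair=("agriculture", "woodland"),
                            by="functional_group")
        assert len(ests) == 2
        assert {e.label.split("=")[-1] for e in ests} == {"microbivore", "predator"}

    def test_absent_factor_errors(self):
        table = _balanced_table(site_sd=0.1)
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        with pytest.raises(ValueError, match="not in the fitted model"):
            emm_contrast(fit, "climate_zone")


class TestAgainstLme4Emmeans:
    def test_contrast_matches_r_oracle(self, tmp_path, metrics_table):
        """Independent route: lme4 REML + emmeans contrast on the same table."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the oracle cross-check")
        table = metrics_table.copy()
        table["log_group_seac"] = np.log(table["group_seac"])
        csv = tmp_path / "metrics.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent("""
            suppressMessages({library(lme4); library(emmeans)})
            args <- commandArgs(trailingOnly=TRUE)
            d <- read.csv(args[1])
            m <- lmer(log_group_seac ~ functional_group * land_use + (1|site_id), data=d, REML=TRUE)
            em <- emmeans(m, ~ land_use)
            ct <- as.data.frame(contrast(em, method=list(avw=c(1,-1))))
            cat(sprintf("%.10f %.10f\\n", ct$estimate[1], ct$SE[1]))
        """))
        out = subprocess.run(
            ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
        )
        r_est, r_se = map(float, out.stdout.split())
        fit = fit_lmm(table, factors=("functional_group", "land_use"))
        est = emm_contrast(fit, "land_use", pair=("agriculture", "woodland"))[0]
        assert est.estimate == pytest.approx(r_est, abs=1e-4)
        assert est.se == pytest.approx(r_se, rel=1e-2)


class TestCovariateModel:
    def test_richness_effect_recovered(self):
        """Richness drives the log metric by construction: positive coefficient."""
        rng = np.random.default_rng(0)
        rows = []
        for s in range(120):
            rich = rng.integers(2, 9)
            b = rng.normal(0, 0.2)
            for g in ["microbivore", "predator"]:
                rows.append(dict(
                    site_id=f"s{s}", land_use="woodland" if s % 2 else "agriculture",
                    climate_zone="temperate" if s % 4 < 2 else "tropical",
                    functional_group=g,
                    family_richness=float(rich),
                    sampling_number=float(rng.integers(10, 40)),
                    log_group_seac=0.5 + 0.15 * rich + b + rng.normal(0, 0.2),
                ))
        fit = covariate_model(pd.DataFrame(rows))
        coef = fit.summary_frame()
        est = coef.loc["family_richness", "estimate"]
        se = coef.loc["family_richness", "se"]
        assert est - 2 * se > 0
        assert est == pytest.approx(0.15, abs=3 * se)

    def test_runs_on_pipeline_output(self, metrics_table):
        """Sampling effort from the metrics table enters the adjusted model
        under its modelling name (family richness is constant in this
        balanced design, so it is left out here)."""
        fit = covariate_model(metrics_table, covariates=("sampling_number",),
                              factors=("functional_group", "land_use"))
        assert "sampling_number" in fit.summary_frame().index

    def test_climate_effect_persists_with_covariates(self):
        """Climate and richness effects both built in: both recovered."""
        rng = np.random.default_rng(1)
        rows = []
        for s in range(150):
            cz = "tropical" if s % 2 else "temperate"
            rich = rng.integers(2, 9)
            b = rng.normal(0, 0.2)
            for g in ["microbivore", "predator"]:
                rows.append(dict(
                    site_id=f"s{s}", land_use="woodland", climate_zone=cz,
                    functional_group=g, family_richness=float(rich),
                    sampling_number=float(rng.integers(10, 40)),
                    log_group_seac=0.5 + 0.1 * rich + 0.35 * (cz == "tropical")
                    + b + rng.normal(0, 0.2),
                ))
        fit = covariate_model(pd.DataFrame(rows),
                              factors=("functional_group", "climate_zone"))
        est = emm_contrast(fit, "climate_zone", pair=("tropical", "temperate"))[0]
        assert est.ci95[0] < 0.35 < est.ci95[1]
        assert est.ci95[0] > 0


class TestDecompositionModels:
    def _decomp(self, expansion_sd, partitioning_sd, seed=0):
        cfg = CommunityConfig(
            strata=(Stratum("temperate", "woodland", 80),),
            groups={
                "microbivore": GroupConfig(base_centroid=(-24.5, 4.5), taxa_count=4,
                                           samples_per_taxon=30),
                "predator": GroupConfig(base_centroid=(-23.5, 7.5), taxa_count=4,
                                        samples_per_taxon=30),
            },
            site_sd=0.0,
            expansion_site_sd=expansion_sd,
            partitioning_site_sd=partitioning_sd,
            fixed_taxon_centroids=True,
        )
        records, _ = generate_records(cfg, seed=seed)
        table, _ = compute_site_metrics(records)
        decomp, _ = decomposition_table(table)
        return decomp

    def test_expansion_only_variation(self):
        """Expansion-only variation: the expansion relation carries the signal
        (positive slope, dominant variance explained); the partitioning
        relation explains ~nothing."""
        decomp = self._decomp(expansion_sd=0.6, partitioning_sd=0.0)
        fits = decomposition_models(decomp)
        assert fits["expansion"].ci95[0] > 0
        assert fits["expansion"].r2_marginal > 0.5
        assert fits["partitioning"].r2_marginal < 0.1

    def test_partitioning_only_variation(self):
        decomp = self._decomp(expansion_sd=0.0, partitioning_sd=0.6, seed=1)
        fits = decomposition_models(decomp)
        assert fits["partitioning"].ci95[0] > 0
        assert fits["partitioning"].r2_marginal > 0.5
        assert fits["expansion"].r2_marginal < 0.1

    def test_constant_response_zero_slopes(self):
        decomp = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(30)] * 2,
            "functional_group": ["microbivore"] * 30 + ["predator"] * 30,
            "log_group_seac": 1.5,
            "mean_taxon_seac": np.linspace(1, 3, 60),
            "dissimilarity": np.linspace(0.5, 2, 60),
        })
        fits = decomposition_models(decomp)
        assert fits["expansion"].slope == pytest.approx(0.0, abs=1e-8)
        assert fits["partitioning"].slope == pytest.approx(0.0, abs=1e-8)

    def test_gradient_preset_recovers_both_relations(self):
        """Independent site-level gradients in within- and between-taxon
        dispersion: both decomposition slopes come out positive."""
        from isoniche import scenario_library

        cfg = scenario_library()["decomposition_gradient"]
        records, _ = generate_records(cfg, seed=4)
        table, _ = compute_site_metrics(records)
        decomp, _ = decomposition_table(table)
        fits = decomposition_models(decomp)
        assert fits["expansion"].ci95[0] > 0
        assert fits["partitioning"].ci95[0] > 0

    def test_r2_bounds(self):
        decomp = self._decomp(expansion_sd=0.5, partitioning_sd=0.5, seed=2)
        fits = decomposition_models(decomp)
        for f in fits.values():
            assert 0.0 <= f.r2_marginal <= f.r2_conditional <= 1.0


class TestMoranI:
    def test_null_statistic_near_expectation(self):
        rng = np.random.default_rng(0)
        lon, lat = rng.uniform(0, 20, 80), rng.uniform(40, 60, 80)
        vals = [
            moran_i(rng.normal(size=80), lon, lat, k=5, n_perm=199,
                    seed=int(rng.integers(2**31 - 1))).i
            for _ in range(50)
        ]
        assert np.mean(vals) == pytest.approx(-1 / 79, abs=0.03)

    def test_latitude_gradient_detected(self):
        rng = np.random.default_rng(1)
        side = np.arange(10)
        lon, lat = np.meshgrid(side * 2.0, 40 + side * 1.5)
        lon, lat = lon.ravel(), lat.ravel()
        z = np.sin(lat / 4.0) + rng.normal(scale=0.1, size=100)
        res = moran_i(z, lon, lat, k=5, n_perm=999, seed=0)
        assert res.i > 0
        assert res.p_value <= 0.005

    def test_knn_matches_brute_force(self):
        rng = np.random.default_rng(2)
        lon, lat = rng.uniform(-5, 5, 50), rng.uniform(45, 55, 50)
        w = knn_weights(lon, lat, k=5)

        def haversine(i, j):
            p1, p2 = np.radians(lat[i]), np.radians(lat[j])
            dl = np.radians(lon[j] - lon[i])
            a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
            return 2 * np.arcsin(np.sqrt(a))

        for i in range(50):
            d = [(haversine(i, j), j) for j in range(50) if j != i]
            nearest = {j for _, j in sorted(d)[:5]}
            assert set(np.nonzero(w[i])[0]) == nearest
            assert w[i].sum() == pytest.approx(1.0)

    def test_constant_residuals_undefined(self):
        lon = np.arange(10.0)
        lat = np.full(10, 45.0) + np.arange(10) * 0.1
        with pytest.raises(ValueError, match="constant"):
            moran_i(np.ones(10), lon, lat, k=3)

    def test_too_few_sites(self):
        with pytest.raises(ValueError, match="k\\+2"):
            moran_i([1.0, 2.0, 0.5], [0, 1, 2], [45, 46, 47], k=5)
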