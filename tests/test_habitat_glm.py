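"""GLM fitting, AIC selection, predictive fit, and pattern classification."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import reefscape.habitat_glm as hg
from reefscape.studies import simulate_abundance_samples
from reefscape.synthetic_data import FishGenModel


def frame(y, response="abundance", **covs):
    n = len(y)
    df = pd.DataFrame({response: y, "reef_type": "natural",
                       "drr": covs.get("drr", np.zeros(n)),
                       "depth": covs.get("depth", np.zeros(n)),
                       "temperature": covs.get("temperature", np.zeros(n)),
                       "sediment_sd": np.nan})
    return df


def make_fit(rows, family="negative_binomial", drr_pred=True):
    """Hand-assembled fit result for classification tests (coef, se, p)."""
    names = ["intercept"] + (["drr", "drr2"] if drr_pred else []) + ["depth"]
    table = pd.DataFrame(rows, index=names, columns=["coef", "se", "p"])
    table["z"] = table["coef"] / table["se"]
    spec = hg.ModelSpec(response="abundance", family=family,
                        predictors=tuple(names[1:]), reef_type="natural")
    return hg.GLMFitResult(spec=spec, table=table[["coef", "se", "z", "p"]],
                           dispersion=2.0, llf=0.0, aic=0.0, n=67,
                           converged=True)


class TestFitGlm:
    def test_poisson_intercept_mle_is_log_mean(self):
        """Closed form: intercept-only Poisson MLE is log(ybar)."""
        samples = frame([2, 4, 6, 2, 4, 6], response="richness")
        spec = hg.ModelSpec(response="richness", family="poisson",
                            predictors=(), reef_type="natural")
        fit = hg.fit_glm(samples, spec)
        assert fit.table.loc["intercept", "coef"] == pytest.approx(np.log(4.0), abs=1e-6)
        assert fit.dispersion is None

    def test_nb_on_poisson_data_has_large_theta(self):
        rng = np.random.default_rng(1)
        for seed in range(3):
            y = np.random.default_rng(seed).poisson(20.0, size=80)
            spec = hg.ModelSpec(response="abundance", family="negative_binomial",
                                predictors=(), reef_type="natural")
            fit = hg.fit_glm(frame(y), spec)
            assert fit.dispersion > 50  # variance ~= mean: essentially Poisson

    def test_wald_z_identity(self):
        rng = np.random.default_rng(2)
        samples = simulate_abundance_samples(60, FishGenModel(), rng)
        spec = hg.ModelSpec(response="abundance", family="negative_binomial",
                            predictors=("drr", "drr2", "depth"))
        fit = hg.fit_glm(samples, spec)
        assert np.allclose(fit.table["z"], fit.table["coef"] / fit.table["se"])
        assert fit.aic == pytest.approx(2 * (len(fit.table) + 1) - 2 * fit.llf)

    def test_coefficient_coverage(self):
        """Planted coefficients recovered within 2 SE in >= 90% of fits."""
        model = FishGenModel(beta0=2.0, beta1=6.0, beta2=-6.0, beta_depth=0.1,
                             beta_temp=0.0)
        truth = {"intercept": 2.0, "drr": 6.0, "drr2": -6.0, "depth": 0.1}
        spec = hg.ModelSpec(response="abundance", family="negative_binomial",
                            predictors=("drr", "drr2", "depth"))
        hits = {k: 0 for k in truth}
        n_seeds = 50
        for seed in range(1, n_seeds + 1):
            rng = np.random.default_rng(seed)
            samples = simulate_abundance_samples(40, model, rng)
            fit = hg.fit_glm(samples, spec)
            for k, v in truth.items():
                row = fit.table.loc[k]
                hits[k] += abs(row["coef"] - v) <= 2 * row["se"]
        for k, h in hits.items():
            assert h / n_seeds >= 0.90, (k, h)

    def test_gamma_requires_positive_and_counts_exclusions(self):
        y = np.array([0.0, 1.2, 3.4, 2.2, 5.1, 0.8, 1.9, 2.5])
        samples = frame(y, response="biomass_kg",
                        depth=np.linspace(10, 30, len(y)))
        spec = hg.ModelSpec(response="biomass_kg", family="gamma",
                            predictors=("depth",))
        fit = hg.fit_glm(samples, spec)
        assert fit.n_excluded_zeros == 1
        assert fit.n == len(y) - 1
        assert fit.dispersion > 0

    def test_integer_response_enforced(self):
        samples = frame([1.5, 2.5, 3.5, 1.5, 2.5, 3.5])
        spec = hg.ModelSpec(response="abundance", family="poisson", predictors=())
        with pytest.raises(ValueError, match="integer"):
            hg.fit_glm(samples, spec)

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="hierarchy"):
            hg.ModelSpec(response="abundance", family="poisson",
                         predictors=("drr2",))

    def test_sediment_only_natural(self):
        with pytest.raises(ValueError, match="natural"):
            hg.ModelSpec(response="abundance", family="poisson",
                         predictors=("sediment_sd",), reef_type="artificial")


class TestModelSelect:
    def test_argmin_aic(self):
        rng = np.random.default_rng(3)
        samples = simulate_abundance_samples(60, FishGenModel(), rng)
        specs = [hg.ModelSpec("abundance", "negative_binomial", p)
                 for p in [("drr", "drr2", "depth"), ("depth",), ()]]
        best, table = hg.model_select(samples, specs)
        assert best.aic == pytest.approx(table["aic"].min())
        assert len(table) == 3

    def test_candidate_hierarchy(self):
        specs = hg.candidate_specs("abundance", "negative_binomial", "natural")
        assert len(specs) == 8
        for s in specs:
            if "drr2" in s.predictors:
                assert "drr" in s.predictors
        art = hg.candidate_specs("richness", "poisson", "artificial")
        assert len(art) == 4
        assert all("sediment_sd" not in s.predictors for s in art)

    def test_noise_predictor_costs_about_two_aic(self):
        """Adding a pure-noise predictor raises AIC by ~2 in expectation."""
        rng = np.random.default_rng(4)
        diffs = []
        for _ in range(100):
            n = 50
            y = rng.poisson(10.0, size=n)
            df = frame(y, response="richness",
                       temperature=rng.normal(size=n))
            base = hg.fit_glm(df, hg.ModelSpec("richness", "poisson", ()))
            noisy = hg.fit_glm(df, hg.ModelSpec("richness", "poisson",
                                                ("temperature",)))
            diffs.append(noisy.aic - base.aic)
        assert 0.5 < np.mean(diffs) < 3.5

    def test_failed_candidate_kept_in_table_with_warning(self):
        samples = frame([2, 3, 4, 5, 3, 2, 4, 3])
        ok = hg.ModelSpec("abundance", "poisson", ())
        too_big = hg.ModelSpec("abundance", "poisson",
                               ("drr", "drr2", "depth", "temperature"))
        with pytest.warns(UserWarning, match="excluded"):
            best, table = hg.model_select(samples, [ok, too_big])
        assert best.spec == ok
        assert not table["converged"].all()
        assert len(table) == 2


class TestAssessFit:
    def test_central_value_p_near_one(self):
        samples = frame([4] * 30)
        fit = hg.fit_glm(samples, hg.ModelSpec("abundance", "poisson", ()))
        pvals, grid = hg.assess_fit(fit)
        assert np.all(pvals > 0.9)
        assert grid["density"].sum() == pytest.approx(1.0, abs=1e-3)

    def test_extreme_observation_small_p(self):
        """Poisson mean 4, observed 15: exact two-sided tail < 0.001."""
        samples = frame([4] * 40 + [15])
        fit = hg.fit_glm(samples, hg.ModelSpec("abundance", "poisson", ()))
        pvals, _ = hg.assess_fit(fit)
        mu = fit.mu[-1]
        exact = 2 * min(stats.poisson.cdf(15, mu), stats.poisson.sf(14, mu))
        assert pvals[-1] == pytest.approx(exact, abs=1e-10)
        assert pvals[-1] < 0.001

    def test_uniform_under_correct_model(self):
        from reefscape.studies import predictive_pvalue_calibration
        assert predictive_pvalue_calibration(n=400, seed=5) > 0.01


class TestClassifyPattern:
    def test_strong_unimodal(self):
        fit = make_fit([(2.26, 0.79, 0.005), (9.72, 2.38, 1e-5),
                        (-9.81, 2.58, 5e-4), (0.11, 0.02, 1e-5)])
        cls = hg.classify_pattern(fit, drr_range=(0.1, 1.0))
        assert cls.pattern == "unimodal"
        assert cls.inflection == pytest.approx(9.72 / (2 * 9.81))
        assert cls.inflection_in_range

    def test_nonsignificant_terms_none(self):
        fit = make_fit([(2.38, 0.95, 0.02), (-0.17, 2.86, 0.95),
                        (2.24, 3.10, 0.47), (0.06, 0.02, 0.05)])
        assert hg.classify_pattern(fit, (0.1, 1.0)).pattern == "none"

    def test_marginal_band_unimodal(self):
        fit = make_fit([(4.37, 0.45, 1e-5), (1.31, 0.63, 0.04),
                        (-0.37, 0.21, 0.08), (0.12, 0.02, 1e-5)])
        assert hg.classify_pattern(fit, (0.2, 3.3)).pattern == "unimodal_marginal"

    def test_linear_only(self):
        fit = make_fit([(1.0, 0.3, 0.01), (2.0, 0.5, 0.001),
                        (-0.1, 0.5, 0.8), (0.1, 0.05, 0.04)])
        assert hg.classify_pattern(fit, (0.1, 1.0)).pattern == "linear"

    def test_quadratic_when_vertex_outside_range(self):
        # both significant but the vertex (2.5) is beyond the observed DRR
        fit = make_fit([(1.0, 0.3, 0.01), (5.0, 0.5, 0.001),
                        (-1.0, 0.3, 0.002), (0.1, 0.05, 0.04)])
        assert hg.classify_pattern(fit, (0.1, 1.0)).pattern == "quadratic"

    def test_no_drr_terms_is_none(self):
        fit = make_fit([(1.0, 0.3, 0.01), (0.1, 0.05, 0.04)], drr_pred=False)
        assert hg.classify_pattern(fit, (0.1, 1.0)).pattern == "none"

    def test_unimodal_detection_power(self):
        """Planted unimodal model detected in >= 80% of seeds at n=67."""
        from reefscape.studies import unimodal_recovery
        df = unimodal_recovery(n_sites=67, seeds=range(1, 21))
        assert (df["pattern"] == "unimodal").mean() >= 0.8
        assert df["rel_vertex_error"].median() < 0.25


class TestPredictionSurface:
    def test_flat_when_only_intercept(self):
        samples = frame([3, 4, 5, 3, 4, 5])
        fit = hg.fit_glm(samples, hg.ModelSpec("abundance", "poisson", ()))
        surface, signs = hg.prediction_surface(fit, samples,
                                               np.linspace(0, 1, 5),
                                               np.linspace(10, 30, 4))
        assert np.allclose(surface, np.exp(fit.table.loc["intercept", "coef"]))
        assert set(np.unique(signs)) <= {-1, 1}
        assert len(signs) == fit.n

    def test_ridge_at_vertex(self):
        rng = np.random.default_rng(6)
        model = FishGenModel(beta0=2.0, beta1=6.0, beta2=-6.0, beta_depth=0.1,
                             beta_temp=0.0)
        samples = simulate_abundance_samples(80, model, rng)
        fit = hg.fit_glm(samples, hg.ModelSpec(
            "abundance", "negative_binomial", ("drr", "drr2", "depth")))
        drr_grid = np.linspace(0.1, 1.0, 91)
        surface, _ = hg.prediction_surface(fit, samples, drr_grid,
                                           np.array([15.0, 25.0]))
        b = fit.table["coef"]
        vertex = -b["drr"] / (2 * b["drr2"])
        for col in range(surface.shape[1]):
            assert drr_grid[np.argmax(surface[:, col])] == pytest.approx(
                vertex, abs=0.011)
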