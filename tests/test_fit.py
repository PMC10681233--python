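"""Model fitting, selection, likelihood-ratio tests and the bootstrap."""

import math

import numpy as np
import pytest

from gibbonascr import (AscrData, AscrFit, CaptureHistory,
                        DensitySpec, HabitatMask, ListeningPost,
                        bootstrap_abundance, fit_model, likelihood_ratio_test,
                        model_selection, negative_log_likelihood,
                        overall_detection_prob)
from gibbonascr.mask import restrict_mask
from gibbonascr.simulate import (SimConfig, histories_from_truth,
                                 parameter_recovery_experiment, simulate_survey)

SMALL = SimConfig(n_sites=5, mask_spacing_m=300.0, window_buffer_m=2500.0,
                  beta=(math.log(0.65 * 1.5),), seed=0)


def prepared_data(cfg, seed, buffer_m=2200.0):
    posts, det_df, truth, masks = simulate_survey(cfg, seed=seed)
    hists = histories_from_truth(truth, posts)
    site_posts = {}
    for p in posts:
        site_posts.setdefault(p.site_id, []).append(p)
    fmasks = {s: restrict_mask(m, site_posts[s], buffer_m)
              for s, m in masks.items()}
    return AscrData(hists, site_posts, fmasks), truth, posts


@pytest.fixture(scope="module")
def small_fit():
    data, truth, posts = prepared_data(SMALL, seed=101)
    fit = fit_model(data)
    return data, fit


class TestFitModel:
    def test_estimates_near_truth_on_one_realization(self, small_fit):
        data, fit = small_fit
        assert fit.convergence["trace"][-1]["success"]
        d_hat = math.exp(fit.theta[0])
        assert 0.4 < d_hat / (0.65 * 1.5) < 2.5
        assert 300.0 < fit.detection.sigma < 800.0
        assert 5.0 < fit.bearing.kappa < 120.0

    def test_aic_identity_and_vcov_shape(self, small_fit):
        _, fit = small_fit
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik,
                                        rel=1e-12)
        assert fit.vcov.shape == (fit.n_params, fit.n_params)
        np.testing.assert_allclose(fit.vcov, fit.vcov.T, atol=1e-12)

    def test_single_point_mask_poisson_mle_identity(self):
        # with one latent location the density MLE satisfies the Poisson
        # closed form D = n / (a p.(s)) at the fitted detection parameters
        posts = [ListeningPost("A", i + 1, 500.0 * i, 0.0, frozenset({1}))
                 for i in range(3)]
        mask = HabitatMask(np.array([400.0]), np.array([600.0]), 0.02)
        rng = np.random.default_rng(8)
        patterns = [(1, 0, 0), (1, 1, 0), (0, 1, 1), (1, 1, 1), (0, 1, 0)]
        hists = []
        for k in range(40):
            om = np.array(patterns[rng.integers(0, len(patterns))])
            hists.append(CaptureHistory("A", 1, f"G{k}", (1, 2, 3), om,
                                        {i + 1: 0.0 for i in range(3) if om[i]}))
        data = AscrData(hists, {"A": posts}, {"A": mask})
        fit = fit_model(data, use_bearings=False)
        p_dot = overall_detection_prob((400.0, 600.0), posts, fit.detection)
        d_closed = len(hists) / (0.02 * p_dot)
        assert math.exp(fit.theta[0]) == pytest.approx(d_closed, rel=1e-3)

    def test_zero_covariate_changes_nothing_but_aic(self, small_fit):
        data, fit = small_fit
        for m in data.site_masks.values():
            m.covariates["null_cov"] = np.zeros(m.n_points)
        # likelihood at beta_null = 0 is identical by construction
        spec0 = fit.density_spec
        spec1 = DensitySpec(("null_cov",), np.append(spec0.beta, 0.0),
                            {"null_cov": (0.0, 1.0)})
        nll0 = negative_log_likelihood(spec0, fit.detection, fit.bearing, data)
        nll1 = negative_log_likelihood(spec1, fit.detection, fit.bearing, data)
        assert nll1 == pytest.approx(nll0, abs=1e-9)
        # a fitted augmented model pays two AIC points for the dead parameter
        fit1 = fit_model(data, ("null_cov",), start=np.insert(fit.theta, 1, 0.0))
        assert fit1.loglik == pytest.approx(fit.loglik, abs=1e-3)
        assert fit1.aic - fit.aic == pytest.approx(2.0, abs=0.01)

    def test_kappa_zero_truth_nested_consistency(self):
        cfg = SimConfig(n_sites=5, mask_spacing_m=300.0, window_buffer_m=2500.0,
                        kappa=0.0, seed=0)
        data, _, _ = prepared_data(cfg, seed=11)
        fit_b = fit_model(data, use_bearings=True)
        fit_nb = fit_model(data, use_bearings=False)
        assert fit_b.bearing.kappa < 0.5
        # uniform-bearing base measure: each detection contributes log(2 pi)
        n_det = sum(int(h.omega.sum()) for h in data.histories)
        adj = fit_b.loglik + n_det * math.log(2 * math.pi)
        assert abs(adj - fit_nb.loglik) < 2.0

    def test_bearings_do_not_hurt_intercept_precision(self, small_fit):
        data, fit_b = small_fit
        fit_nb = fit_model(data, use_bearings=False)
        se_b = fit_b.se[0]
        se_nb = fit_nb.se[0]
        assert se_b <= se_nb * 1.05


class TestModelSelection:
    def test_pool_of_two_gives_four_ranked_models(self, small_fit):
        data, _ = small_fit
        for m in data.site_masks.values():
            if "null_cov" not in m.covariates:
                m.covariates["null_cov"] = np.zeros(m.n_points)
        tab = model_selection(data, ["canopy_height", "null_cov"])
        assert len(tab) == 4
        assert tab.converged.all()
        np.testing.assert_allclose(
            tab.aic, 2 * tab.n_params - 2 * tab.loglik, rtol=1e-12)
        assert tab.delta_aic.iloc[0] == 0.0
        assert tab.delta_aic.is_monotonic_increasing
        # adding a covariate can only raise the maximized log-likelihood
        ll = {tuple(r.model): r.loglik for r in tab.itertuples()}
        for terms, l in ll.items():
            for other, l2 in ll.items():
                if set(terms) < set(other):
                    assert l2 >= l - 1e-3

    def test_forest_counts_two_parameters(self, small_fit):
        data, fit0 = small_fit
        fitf = fit_model(data, ("forest",))
        assert fitf.n_params == fit0.n_params + 2


class TestLikelihoodRatio:
    def test_identical_fits_give_zero(self, small_fit):
        _, fit = small_fit
        stat, df, p = likelihood_ratio_test(
            AscrFit(fit.density_spec, fit.detection, fit.bearing, fit.loglik,
                    fit.n_params + 2, fit.aic, fit.vcov, fit.param_names,
                    fit.theta),
            fit)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail(self, small_fit):
        _, fit = small_fit
        full = AscrFit(DensitySpec(("forest",), np.zeros(3)), fit.detection,
                       fit.bearing, fit.loglik + 3.0, fit.n_params + 2,
                       0.0, fit.vcov, fit.param_names, fit.theta)
        stat, df, p = likelihood_ratio_test(full, fit)
        assert stat == pytest.approx(6.0) and df == 2
        assert p == pytest.approx(0.0498, abs=2e-4)

    def test_non_nested_rejected(self, small_fit):
        _, fit = small_fit
        other = AscrFit(DensitySpec(("elevation",), np.zeros(2)), fit.detection,
                        fit.bearing, fit.loglik, fit.n_params, fit.aic,
                        fit.vcov, fit.param_names, fit.theta)
        reduced = AscrFit(DensitySpec(("canopy_height",), np.zeros(2)),
                          fit.detection, fit.bearing, fit.loglik, fit.n_params,
                          fit.aic, fit.vcov, fit.param_names, fit.theta)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(other, reduced)


class TestBootstrap:
    def park_mask(self):
        x, y = np.meshgrid(np.arange(0, 5000, 500.0), np.arange(0, 5000, 500.0))
        return HabitatMask(x.ravel(), y.ravel(), 0.25)

    def test_degenerate_vcov_collapses_interval(self, small_fit):
        _, fit = small_fit
        frozen = AscrFit(fit.density_spec, fit.detection, fit.bearing,
                         fit.loglik, fit.n_params, fit.aic,
                         np.zeros_like(fit.vcov), fit.param_names, fit.theta)
        est = bootstrap_abundance(frozen, 0.65, self.park_mask(), B=64, seed=1)
        assert est.tcg_ci[0] == pytest.approx(est.tcg, rel=1e-12)
        assert est.tgg_ci[1] == pytest.approx(est.tgg, rel=1e-12)
        assert est.tgg == pytest.approx(est.tcg / 0.65, rel=1e-12)

    def test_interval_brackets_point_and_cv_definition(self, small_fit):
        _, fit = small_fit
        est = bootstrap_abundance(fit, 0.65, self.park_mask(), B=200, seed=3)
        assert est.tcg_ci[0] <= est.tcg <= est.tcg_ci[1]
        assert est.tgg_ci[0] <= est.tgg <= est.tgg_ci[1]
        assert est.tcg_cv == pytest.approx(est.tcg_se / est.tcg, rel=1e-12)
        assert est.tgg_cv == pytest.approx(est.tgg_se / est.tgg, rel=1e-12)
        assert est.mean_daily_calling_density == pytest.approx(
            est.tcg / self.park_mask().total_area_km2, rel=1e-12)

    def test_indefinite_vcov_rejected(self, small_fit):
        from gibbonascr.fit import BootstrapError
        _, fit = small_fit
        bad = -np.eye(fit.n_params)
        broken = AscrFit(fit.density_spec, fit.detection, fit.bearing,
                         fit.loglik, fit.n_params, fit.aic, bad,
                         fit.param_names, fit.theta)
        with pytest.raises(BootstrapError):
            bootstrap_abundance(broken, 0.65, self.park_mask(), B=16, seed=0)


class TestRecoveryHarness:
    def test_zero_replicates_empty_report(self):
        out = parameter_recovery_experiment(SMALL, 0, seed=1)
        assert out["replicates"].empty and out["summary"] == {}

    def test_two_replicates_report_fields(self):
        cfg = SimConfig(n_sites=3, mask_spacing_m=300.0, window_buffer_m=2500.0,
                        seed=0)
        out = parameter_recovery_experiment(cfg, 2, seed=4,
                                            mask_buffer_m=2200.0)
        reps = out["replicates"]
        assert len(reps) == 2
        for col in ("D", "Dg", "lambda0", "sigma", "kappa", "p"):
            assert col in reps.columns
            assert col in out["summary"]
        assert (reps["Dg_lo"] <= reps["Dg_hi"]).all()
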