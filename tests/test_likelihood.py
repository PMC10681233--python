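"""The marginal ASCR likelihood against independent oracles, plus the
density surface and its integral."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from gibbonascr import (AscrData, BearingParams, CaptureHistory, DensitySpec,
                        DetectionParams, HabitatMask, ListeningPost, build_mask,
                        density_surface, expected_calling_groups,
                        negative_log_likelihood)
from gibbonascr.fit import CoverageError
from conftest import random_micro_instance
from oracles import brute_force_nll


class TestDensitySurface:
    def test_constant_model(self):
        m = HabitatMask(np.arange(5.0), np.zeros(5), 0.01)
        spec = DensitySpec((), [np.log(0.32)])
        np.testing.assert_allclose(density_surface(m, spec), 0.32)

    def test_forest_contrast_ratio(self):
        m = HabitatMask(np.array([0.0, 100.0]), np.zeros(2), 0.01,
                        {"forest_class": np.array(["F1_evergreen",
                                                   "F2_semi_evergreen"],
                                                  dtype=object)})
        spec = DensitySpec(("forest",), [0.0, -1.45, 0.0])
        d = density_surface(m, spec)
        assert d[0] / d[1] == pytest.approx(math.exp(1.45), rel=1e-12)
        assert d[0] / d[1] == pytest.approx(4.3, abs=0.05)

    def test_all_zero_beta_gives_unit_density(self):
        m = HabitatMask(np.arange(3.0), np.zeros(3), 0.01,
                        {"canopy_height": np.array([5.0, 10.0, 15.0])})
        spec = DensitySpec(("canopy_height",), [0.0, 0.0])
        np.testing.assert_allclose(density_surface(m, spec), 1.0)


class TestExpectedCallingGroups:
    def test_constant_density_over_park(self):
        # 0.32 calling groups/km^2 over 575 km^2 -> 184 on a given day
        m = build_mask(box(0, 0, 25000, 23000), 500.0)
        spec = DensitySpec((), [np.log(0.32)])
        assert expected_calling_groups(m, spec) == pytest.approx(184.0, rel=1e-9)

    def test_zero_density(self):
        m = HabitatMask(np.arange(4.0), np.zeros(4), 0.01)
        assert expected_calling_groups(m, DensitySpec((), [-np.inf])) == 0.0

    def test_exponential_strip_matches_analytic_integral(self):
        # D(x) = exp(a + b x) on [0, W] x [0, H]: integral = H e^a (e^{bW}-1)/b
        m = build_mask(box(0, 0, 10000, 2000), 50.0)
        a, b = -1.0, 2e-4  # b per metre
        m.covariates["xm"] = m.x
        spec = DensitySpec(("xm",), [a, b])
        got = expected_calling_groups(m, spec)
        H, W = 2.0, 10.0  # km
        bk = b * 1000.0
        want = H * math.exp(a) * (math.exp(bk * W) - 1) / bk
        assert got == pytest.approx(want, rel=2e-4)

    def test_linear_in_density(self):
        m = HabitatMask(np.arange(6.0) * 100, np.zeros(6), 0.04,
                        {"canopy_height": np.linspace(-1, 1, 6)})
        spec = DensitySpec(("canopy_height",), [0.3, 0.7])
        spec2 = DensitySpec(("canopy_height",), [0.3 + np.log(2), 0.7])
        assert expected_calling_groups(m, spec2) == pytest.approx(
            2 * expected_calling_groups(m, spec), rel=1e-12)

    def test_missing_covariate_is_coverage_error(self):
        m = HabitatMask(np.arange(4.0), np.zeros(4), 0.01)
        with pytest.raises(CoverageError, match="dist_logging"):
            expected_calling_groups(m, DensitySpec(("dist_logging",), [0.0, 0.1]))


class TestLikelihoodOracle:
    def test_matches_brute_force_on_random_micro_instances(self):
        rng = np.random.default_rng(20240917)
        for trial in range(100):
            data = random_micro_instance(rng)
            terms = ("cv", "forest") if trial % 2 else ()
            kb = 1 + (3 if terms else 0)
            spec = DensitySpec(terms, rng.normal(0, 0.5, kb))
            det = DetectionParams(float(rng.uniform(0.5, 20)),
                                  float(rng.uniform(200, 900)))
            bear = BearingParams(float(rng.uniform(0.1, 40))) if trial % 3 else None
            ours = negative_log_likelihood(spec, det, bear, data)
            oracle = brute_force_nll(data, spec, det, bear)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_single_point_mask_closed_form(self):
        # one latent location s: the likelihood factorizes into a Poisson
        # term and Bernoulli/von-Mises products evaluable by hand
        posts = [ListeningPost("A", 1, 0.0, 0.0, frozenset({1})),
                 ListeningPost("A", 2, 500.0, 0.0, frozenset({1}))]
        mask = HabitatMask(np.array([200.0]), np.array([300.0]), 0.02)
        h = CaptureHistory("A", 1, "G1", (1, 2), np.array([1, 0]),
                           {1: 40.0})
        data = AscrData([h], {"A": posts}, {"A": mask})
        D, lam0, sig, kap = 1.7, 3.0, 400.0, 12.0
        spec = DensitySpec((), [math.log(D)])
        nll = negative_log_likelihood(spec, DetectionParams(lam0, sig),
                                      BearingParams(kap), data)

        d1 = math.hypot(200, 300)
        d2 = math.hypot(200 - 500, 300)
        g1 = 1 - math.exp(-lam0 * math.exp(-d1**2 / (2 * sig**2)))
        g2 = 1 - math.exp(-lam0 * math.exp(-d2**2 / (2 * sig**2)))
        a = 0.02
        lam = a * D * (1 - (1 - g1) * (1 - g2))
        theta_true = math.atan2(200.0, 300.0)
        from scipy.special import i0
        vm = math.exp(kap * math.cos(math.radians(40.0) - theta_true)) / (
            2 * math.pi * i0(kap))
        hand = lam - math.log(a * D * g1 * (1 - g2) * vm)
        assert nll == pytest.approx(hand, rel=1e-12)

    def test_no_bearings_equals_bearing_free_likelihood(self, three_posts):
        mask = HabitatMask(np.linspace(-500, 1500, 9), np.full(9, 400.0), 0.04)
        h = CaptureHistory("A", 1, "G1", (1, 2, 3), np.array([0, 1, 1]),
                           {2: 10.0, 3: 350.0})
        h_nb = CaptureHistory("A", 1, "G1", (1, 2, 3), np.array([0, 1, 1]),
                              {2: 10.0, 3: 350.0})
        data = AscrData([h], {"A": three_posts}, {"A": mask})
        spec = DensitySpec((), [0.2])
        det = DetectionParams(5.0, 500.0)
        with_kappa_none = negative_log_likelihood(spec, det, None, data)
        oracle = brute_force_nll(data, spec, det, None)
        assert with_kappa_none == pytest.approx(oracle, rel=1e-12)
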