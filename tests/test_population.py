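"""Log-normal population layer: CV conversions, sampling, density."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import lognorm

from popdesign import (PopulationParams, sigma_to_cv, cv_to_sigma,
                       sample_individuals, log_density,
                       wtc_population_layout, toy_population_layout, SIGMA_MAX)
from popdesign.circuits import WTC_VARIABLE


def _gamma(sigma=0.1, cov_mode="scalar", medians=(1.12, 0.79, 0.84, 1.28, 0.0087, 0.006)):
    cov = sigma ** 2 if cov_mode == "scalar" else np.full(6, sigma) ** 2
    return PopulationParams(variable=WTC_VARIABLE,
                            mean_log=np.log(medians),
                            cov_mode=cov_mode, cov=cov,
                            shared={"theta_Tet": 0.006, "theta_Tup": 0.5e-4})


class TestCVConversion:
    def test_zero_maps_to_zero(self):
        assert sigma_to_cv(0.0) == 0.0
        assert cv_to_sigma(0.0) == 0.0

    def test_known_value(self):
        assert sigma_to_cv(0.1) == pytest.approx(math.sqrt(math.e ** 0.01 - 1))
        assert float(sigma_to_cv(0.1)) == pytest.approx(0.100250, abs=1e-6)

    def test_cv_of_one_is_sigma_max(self):
        assert cv_to_sigma(1.0) == pytest.approx(SIGMA_MAX)

    def test_small_sigma_approximation(self):
        # the CV ~ sigma shortcut is accurate to < 0.6% for sigma <= 0.1
        sig = np.linspace(1e-4, 0.1, 50)
        rel = np.abs(sigma_to_cv(sig) - sig) / sig
        assert np.all(rel < 0.006)

    @given(st.floats(min_value=0.0, max_value=2.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, sigma):
        assert float(cv_to_sigma(sigma_to_cv(sigma))) == pytest.approx(
            sigma, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sigma_to_cv(-0.1)
        with pytest.raises(ValueError):
            cv_to_sigma(-0.1)


class TestSampling:
    def test_zero_variance_returns_medians(self, rng):
        g = _gamma(sigma=0.0)
        p = sample_individuals(g, 5, rng)
        for j, name in enumerate(WTC_VARIABLE):
            np.testing.assert_allclose(p[name], math.exp(g.mean_log[j]))
        assert p["theta_Tet"] == 0.006

    def test_moments_recover_configured_cv(self, rng):
        cv = 0.2
        g = _gamma(sigma=float(cv_to_sigma(cv)))
        p = sample_individuals(g, 10_000, rng)
        for name in WTC_VARIABLE:
            observed = np.std(p[name]) / np.mean(p[name])
            assert observed == pytest.approx(cv, rel=0.05)

    def test_median_recovers_location(self, rng):
        g = _gamma(sigma=0.3)
        p = sample_individuals(g, 10_000, rng)
        assert np.median(p["k_C"]) == pytest.approx(0.84, rel=0.03)

    def test_crn_makes_draws_deterministic(self):
        g = _gamma(sigma=0.1)
        crn = np.random.default_rng(3).standard_normal((50, 6))
        p1 = sample_individuals(g, 50, crn)
        p2 = sample_individuals(g, 50, crn)
        for name in WTC_VARIABLE:
            np.testing.assert_array_equal(p1[name], p2[name])

    def test_scalar_equals_diagonal_with_equal_entries(self):
        crn = np.random.default_rng(4).standard_normal((100, 6))
        ps = sample_individuals(_gamma(0.15, "scalar"), 100, crn)
        pd = sample_individuals(_gamma(0.15, "diagonal"), 100, crn)
        for name in WTC_VARIABLE:
            np.testing.assert_array_equal(ps[name], pd[name])

    def test_all_draws_strictly_positive(self, rng):
        p = sample_individuals(_gamma(sigma=0.8), 1000, rng)
        for name in WTC_VARIABLE:
            assert np.all(p[name] > 0)

    def test_invalid_covariance_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not positive definite
        g = PopulationParams(variable=("k", "d"), mean_log=np.zeros(2),
                             cov_mode="full", cov=bad)
        with pytest.raises(ValueError):
            g.chol()


class TestLogDensity:
    def test_maximal_at_median_for_scalar_cov(self):
        g = _gamma(sigma=0.2)
        centre = np.exp(g.mean_log)
        base = log_density(g, centre)
        rng = np.random.default_rng(11)
        for _ in range(20):
            jitter = centre * np.exp(0.05 * rng.standard_normal(6))
            # density of the underlying normal is maximal at the median
            assert log_density(g, jitter) - (-np.sum(np.log(jitter))) <= \
                base - (-np.sum(np.log(centre))) + 1e-12

    def test_non_positive_beta_gives_minus_inf(self):
        g = _gamma()
        bad = np.exp(g.mean_log).copy()
        bad[0] = 0.0
        assert log_density(g, bad) == -np.inf

    def test_univariate_slice_integrates_to_one(self):
        g = PopulationParams(variable=("k",), mean_log=np.array([0.1]),
                             cov_mode="scalar", cov=0.3 ** 2)
        val, err = quad(lambda b: math.exp(log_density(g, np.array([b]))),
                        1e-6, 50.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_diagonal_mode_factorizes(self):
        sig = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.05])
        g = PopulationParams(variable=WTC_VARIABLE,
                             mean_log=np.log([1.12, 0.79, 0.84, 1.28, 0.0087, 0.006]),
                             cov_mode="diagonal", cov=sig ** 2)
        beta = np.exp(g.mean_log + 0.1)
        expected = sum(
            lognorm(s=s, scale=math.exp(m)).logpdf(b)
            for s, m, b in zip(sig, g.mean_log, beta))
        assert log_density(g, beta) == pytest.approx(expected, rel=1e-12)


class TestLayouts:
    def test_scalar_mode_has_five_dimensions(self):
        lay = wtc_population_layout("scalar")
        assert lay.ndim == 5
        assert lay.names[-1] == "sigma"

    def test_diagonal_mode_has_ten_dimensions(self):
        assert wtc_population_layout("diagonal").ndim == 10

    def test_vector_round_trip(self):
        lay = wtc_population_layout("scalar")
        x = np.array([-2.1, -2.2, -2.2, -4.3, -1.5])
        g = lay.gamma_from_vector(x)
        np.testing.assert_allclose(lay.vector_from_gamma(g), x, rtol=1e-12)
        assert g.shared["theta_Tet"] == pytest.approx(10 ** -2.2)
        assert math.sqrt(g.cov) == pytest.approx(10 ** -1.5)

    def test_toy_mean_only_is_one_dimensional(self):
        lay = toy_population_layout(mode="mean-only", fixed_sigma=0.2,
                                    d_variable=False)
        assert lay.ndim == 1
        g = lay.gamma_from_vector(np.array([0.5]))
        assert g.mean_log[0] == pytest.approx(0.5 * math.log(10))
        assert g.cov == pytest.approx(0.04)
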