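"""Circuit model unit and property tests: binding fraction, ODE right-hand
side, steady-state solvers and their agreement with independent oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

from popdesign import (IndividualParams, active_fraction, wtc_rhs,
                       steady_state_output, dose_response, toy_model_output,
                       wtc_individual_layout, get_model, WTCModel, ToyModel)
from popdesign.circuits import wtc_batch_steady_state


K_A = 144.37


def _free_repressor_oracle(R_total, a, K_a):
    """Independent root of the rapid-equilibrium binding quadratic.

    With total repressor T and total inducer a, the bound complex x solves
    K_a*(T - x)*(a - x) = x; the active fraction is (T - x)/T.
    """
    def g(x):
        return K_a * (R_total - x) * (a - x) - x
    x = brentq(g, 0.0, min(R_total, a), xtol=1e-15, rtol=1e-14)
    return (R_total - x) / R_total


class TestActiveFraction:
    def test_no_inducer_gives_fully_active_repressor(self):
        assert active_fraction(1.0, 1.0, 0.0, K_A) == pytest.approx(1.0)

    def test_saturating_inducer_inactivates(self):
        f = active_fraction(1.0, 1.0, 1e9, K_A)
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_matches_binding_quadratic_oracle(self):
        f = active_fraction(0.5, 0.617, 25.0, K_A)
        expected = _free_repressor_oracle(0.5 + 0.617, 25.0, K_A)
        assert f == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("a", [0.0, 1.0, 150.0])
    def test_zero_repressor_limit(self, a):
        # continuous limit 1/(1 + K_a a) of the quadratic root as T -> 0
        assert active_fraction(0.0, 0.0, a, K_A) == pytest.approx(
            1.0 / (1.0 + K_A * a))

    def test_monotone_non_increasing_in_dose(self):
        doses = np.linspace(0.0, 300.0, 121)
        f = active_fraction(0.5, 0.617, doses, K_A)
        assert f[0] == pytest.approx(1.0)
        assert np.all(np.diff(f) <= 1e-12)
        assert np.all((0.0 <= f) & (f <= 1.0))


class TestWTCRhs:
    def test_tup_balance_is_linear(self, fitted_params):
        p = fitted_params
        state = np.array([0.3, p.k_Tup / p.d_Tup, 10.0])
        assert wtc_rhs(state, 20.0, p)[1] == pytest.approx(0.0, abs=1e-14)

    def test_tup_steady_state_closed_form(self, fitted_params):
        assert fitted_params.k_Tup / fitted_params.d_Tup == pytest.approx(0.6171875)

    def test_removing_repression_recovers_max_production(self, fitted_params):
        p = fitted_params.replace(theta_Tet=1e15, theta_Tup=1e15)
        d = wtc_rhs(np.zeros(3), 10.0, p)
        assert d[0] == pytest.approx(p.k_Tet)
        assert d[2] == pytest.approx(p.k_C)

    def test_rejects_non_finite_parameters(self):
        with pytest.raises(ValueError):
            IndividualParams(k_Tet=np.nan)
        with pytest.raises(ValueError):
            IndividualParams(d_C=-1.0)


class TestSteadyState:
    def test_unrepressed_citrine_is_production_over_degradation(self, fitted_params):
        p = fitted_params.replace(theta_Tet=1e15, theta_Tup=1e15)
        for a in (0.0, 80.0):
            y, ok = steady_state_output(p, a)
            assert ok and y == pytest.approx(p.k_C / p.d_C, rel=1e-9)

    def test_integration_agrees_with_root_finding(self, fitted_params):
        """Reference ODE integration vs the algebraic fast path, random draws."""
        layout = wtc_individual_layout()
        rng = np.random.default_rng(7)
        lo, hi = layout.sampling_bounds()
        n_checked = 0
        for _ in range(100):
            x = rng.uniform(lo, hi)
            p = IndividualParams.from_dict(layout.params_from_vector(x))
            a = float(rng.uniform(0.0, 150.0))
            y_fast, _ = steady_state_output(p, a, method="fastpath")
            y_ode, ok = steady_state_output(p, a, method="integrate")
            assert ok
            assert y_ode == pytest.approx(y_fast, rel=1e-6, abs=1e-9)
            n_checked += 1
        assert n_checked == 100

    def test_dose_response_monotone_for_fitted_circuit(self, fitted_params):
        dr = dose_response(fitted_params, np.arange(0.0, 151.0, 25.0))
        assert np.all(np.diff(dr.outputs) > 0)
        assert np.all(dr.converged)

    def test_fitted_curve_tracks_reference_line(self, fitted_params, base_reference):
        dr = dose_response(fitted_params, base_reference.doses)
        assert np.max(np.abs(dr.outputs - base_reference.values)) < 6.0

    def test_dose_validation(self, fitted_params):
        with pytest.raises(ValueError):
            dose_response(fitted_params, [-1.0, 5.0])
        with pytest.raises(ValueError):
            dose_response(fitted_params, [10.0, 5.0])
        with pytest.raises(ValueError):
            steady_state_output(fitted_params, -0.5)

    def test_batch_solver_matches_scalar_path(self, fitted_params, rng):
        layout = wtc_individual_layout()
        lo, hi = layout.sampling_bounds()
        doses = np.array([0.0, 50.0, 150.0])
        X = rng.uniform(lo, hi, size=(20, 4))
        ps = [IndividualParams.from_dict(layout.params_from_vector(x)) for x in X]
        batch = wtc_batch_steady_state(
            doses,
            **{f: np.array([getattr(p, f) for p in ps])
               for f in ("k_Tet", "k_Tup", "k_C", "d_Tup", "d_Tet", "d_C",
                         "theta_Tet", "theta_Tup")},
            n_Tet=1.57, n_Tup=1.57, K_a=K_A)
        for i, p in enumerate(ps):
            single = dose_response(p, doses).outputs
            np.testing.assert_allclose(batch[i], single, rtol=1e-9)


class TestToyModel:
    def test_constant_mode_output(self):
        assert toy_model_output(1.0, 1.0, 37.0) == pytest.approx(1.0)
        assert toy_model_output(3.0, 2.0, 0.0) == pytest.approx(1.5)

    def test_hill_mode_half_saturation(self):
        assert toy_model_output(2.0, 1.0, 50.0, a_half=50.0, mode="hill") \
            == pytest.approx(1.0)

    def test_model_factory(self):
        assert isinstance(get_model("wtc"), WTCModel)
        assert isinstance(get_model("toy"), ToyModel)
        with pytest.raises(ValueError):
            get_model("nope")
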