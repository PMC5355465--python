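"""Nonlinear metabolism model, steady state, stability, tracer coupling
and the analytic linearized solution."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from iggkin.kinetics import (DEFAULT_PARAMETERS, MetabolicParameters,
                             SystemState, biexponential_constants,
                             coupled_tracer_rhs, endogenous_rhs, is_stable,
                             linear_tracer_solution, linearization_error,
                             routh_hurwitz_coefficients, simulate_coupled,
                             steady_state, net_elimination_rate)
from .conftest import random_valid_parameters


class TestValidationAndStability:
    def test_default_parameters_stable(self, params):
        result = is_stable(params)
        assert result.stable
        assert params.k31 - params.Vmax / params.KM == pytest.approx(0.16 - 40 / 270)

    def test_net_elimination_violation_diagnosed(self):
        bad = MetabolicParameters(k12=0.38, k21=0.42, k31=0.1, Vmax=40, KM=270)
        result = is_stable(bad)
        assert not result.stable
        assert "net elimination" in result.diagnostic

    @pytest.mark.parametrize("field", ["k12", "k21", "k31", "Vmax", "KM"])
    def test_nonpositive_parameter_diagnosed(self, params, field):
        bad = MetabolicParameters(**{**params.to_dict(), field: 0.0})
        result = is_stable(bad)
        assert not result.stable
        assert field in result.diagnostic

    def test_validate_raises_with_condition_name(self, params):
        bad = MetabolicParameters(**{**params.to_dict(), "Vmax": -1.0})
        with pytest.raises(ValueError, match="Vmax"):
            endogenous_rhs(SystemState(1.0, 1.0), bad, 0.0)


class TestEndogenousModel:
    def test_rhs_zero_at_steady_state(self, params):
        ss = steady_state(params, 15.0)
        dx1, dx2 = endogenous_rhs(ss, params, 15.0)
        assert abs(dx1) < 1e-9 and abs(dx2) < 1e-9

    def test_rhs_empty_system_fills_plasma_first(self, params):
        dx1, dx2 = endogenous_rhs(SystemState(0.0, 0.0), params, 15.0)
        assert dx1 == pytest.approx(15.0)
        assert dx2 == 0.0

    def test_rhs_hand_arithmetic_peripheral_balance(self, params):
        # x2 chosen so the peripheral compartment is almost balanced
        _, dx2 = endogenous_rhs(SystemState(200.0, 221.05), params, 15.0)
        assert dx2 == pytest.approx(0.42 * 200 - 0.38 * 221.05, abs=1e-12)
        assert abs(dx2) < 2e-3

    def test_steady_state_reference_value(self, params):
        # production tuned to the lowest plasma quantity seen in the data
        assert steady_state(params, 0.0727).x1 == pytest.approx(5.0, abs=5e-3)

    def test_steady_state_zero_production(self, params):
        assert steady_state(params, 0.0) == SystemState(0.0, 0.0)

    def test_steady_state_matches_root_finding_oracle(self, params):
        I0 = 15.0
        ratio = params.k21 / params.k12

        def plasma_balance(x1):
            return endogenous_rhs(SystemState(x1, ratio * x1), params, I0)[0]

        x_oracle = brentq(plasma_balance, 1e-9, 1e6, xtol=1e-12)
        assert steady_state(params, I0).x1 == pytest.approx(x_oracle, rel=1e-9)

    def test_steady_state_zeroes_rhs_for_random_parameters(self, rng):
        for _ in range(100):
            p = random_valid_parameters(rng)
            I0 = rng.uniform(0.1, 100.0)
            ss = steady_state(p, I0)
            dx1, dx2 = endogenous_rhs(ss, p, I0)
            assert abs(dx1) / max(I0, 1.0) < 1e-9
            assert abs(dx2) / max(I0, 1.0) < 1e-9

    def test_mass_balance_decay_without_production(self, params, rng):
        for _ in range(20):
            x1 = rng.uniform(0.0, 2000.0)
            x2 = rng.uniform(0.0, 2000.0)
            dx1, dx2 = endogenous_rhs(SystemState(x1, x2), params, 0.0)
            expected = -net_elimination_rate(params, x1) * x1
            assert dx1 + dx2 == pytest.approx(expected, rel=1e-12, abs=1e-12)
            assert dx1 + dx2 <= 1e-12


class TestRouthHurwitz:
    def test_a2_is_one(self, params):
        assert routh_hurwitz_coefficients(params, 100.0)[2] == 1.0

    def test_positive_for_random_valid_parameters(self, rng):
        for _ in range(100):
            p = random_valid_parameters(rng)
            x1_hat = steady_state(p, rng.uniform(0.1, 50.0)).x1
            a0, a1, a2 = routh_hurwitz_coefficients(p, x1_hat)
            assert a0 > 0 and a1 > 0 and a2 == 1.0

    def test_matches_characteristic_polynomial_of_jacobian(self, params):
        x1_hat = steady_state(params, 15.0).x1
        # numeric Jacobian of the nonlinear right-hand side at equilibrium
        h = 1e-6
        J = np.zeros((2, 2))
        base = SystemState(x1_hat, params.k21 / params.k12 * x1_hat)
        for j in range(2):
            up = list(base)
            dn = list(base)
            up[j] += h
            dn[j] -= h
            fu = endogenous_rhs(SystemState(*up), params, 15.0)
            fd = endogenous_rhs(SystemState(*dn), params, 15.0)
            J[:, j] = (np.array(fu) - np.array(fd)) / (2 * h)
        coeffs = np.poly(J)  # [1, a1, a0]
        a0, a1, _ = routh_hurwitz_coefficients(params, x1_hat)
        assert a1 == pytest.approx(coeffs[1], rel=1e-5)
        assert a0 == pytest.approx(coeffs[2], rel=1e-5)


class TestCoupledTracer:
    def test_zero_tracer_reduces_to_endogenous_model(self, params):
        endo = SystemState(300.0, 280.0)
        d_tracer, d_endo = coupled_tracer_rhs(SystemState(0.0, 0.0), endo,
                                              params, 15.0)
        assert d_tracer == SystemState(0.0, 0.0)
        assert tuple(d_endo) == pytest.approx(endogenous_rhs(endo, params, 15.0))

    def test_sum_obeys_single_species_dynamics(self, params, rng):
        for _ in range(20):
            tracer = SystemState(rng.uniform(0, 10), rng.uniform(0, 10))
            endo = SystemState(rng.uniform(1, 1000), rng.uniform(1, 1000))
            d_t, d_e = coupled_tracer_rhs(tracer, endo, params, 15.0)
            total = SystemState(tracer.x1 + endo.x1, tracer.x2 + endo.x2)
            d_total = endogenous_rhs(total, params, 15.0)
            assert d_t.x1 + d_e.x1 == pytest.approx(d_total[0], rel=1e-12)
            assert d_t.x2 + d_e.x2 == pytest.approx(d_total[1], rel=1e-12)

    def test_observed_fractions_start_at_one(self, params):
        times = np.array([0.0, 1.0, 5.0, 20.0])
        y1, y2 = simulate_coupled(params, 15.0, 0.005, times)
        assert y1[0] == pytest.approx(1.0)
        assert y2[0] == pytest.approx(1.0)
        assert np.all(y2 - y1 >= -1e-12)  # body fraction includes plasma
        assert np.all((y1 > 0) & (y1 <= 1.0 + 1e-9))

    def test_frozen_endogenous_option_close_to_full_coupling(self, params):
        times = np.linspace(0.1, 30, 40)
        y1_full, _ = simulate_coupled(params, 15.0, 0.005, times)
        y1_frozen, _ = simulate_coupled(params, 15.0, 0.005, times,
                                        freeze_endogenous=True)
        assert np.max(np.abs(y1_full - y1_frozen)) < 1e-6


class TestLinearSolution:
    def test_initial_conditions(self, params):
        x1P, x2P = linear_tracer_solution(params, 200.0, np.array([0.0]))
        assert x1P[0] == pytest.approx(1.0)
        assert x2P[0] == pytest.approx(0.0, abs=1e-14)

    def test_vieta_identities(self, params):
        sol = biexponential_constants(params, 200.0)
        f = net_elimination_rate(params, 200.0)
        assert sol.lambda1 * sol.lambda2 == pytest.approx(params.k12 * f, rel=1e-12)
        assert sol.lambda1 + sol.lambda2 == pytest.approx(
            -(params.k12 + params.k21 + f), rel=1e-12)
        assert sol.lambda1 < sol.lambda2 < 0

    def test_slow_eigenvalue_matches_numeric_eigensolve(self, params):
        f = net_elimination_rate(params, 200.0)
        A = np.array([[-(params.k21 + f), params.k12],
                      [params.k21, -params.k12]])
        lam = np.sort(np.linalg.eigvals(A))
        sol = biexponential_constants(params, 200.0)
        assert sol.lambda1 == pytest.approx(lam[0], rel=1e-12)
        assert sol.lambda2 == pytest.approx(lam[1], rel=1e-12)
        # slow eigenvalue gives the ~20.5 day half-life at x1E = 200
        assert -np.log(2) / sol.lambda2 == pytest.approx(20.48, abs=0.01)

    def test_analytic_matches_numeric_integration(self, rng):
        times = np.linspace(0.0, 50.0, 51)
        for _ in range(10):
            p = random_valid_parameters(rng)
            x1E = rng.uniform(5.0, 2000.0)
            f = net_elimination_rate(p, x1E)
            A = np.array([[-(p.k21 + f), p.k12], [p.k21, -p.k12]])
            num = solve_ivp(lambda t, y: A @ y, (0, 50), [1.0, 0.0],
                            t_eval=times, rtol=1e-10, atol=1e-12,
                            method="LSODA")
            x1P, x2P = linear_tracer_solution(p, x1E, times)
            assert np.max(np.abs(x1P - num.y[0])) < 1e-6
            assert np.max(np.abs(x2P - num.y[1])) < 1e-6


class TestLinearizationValidity:
    def test_small_dose_discrepancy_below_one_percent(self, params):
        times = np.linspace(0.1, 30.0, 60)
        err = linearization_error(params, 0.0727, 0.01, times)
        assert err < 0.01

    def test_large_dose_much_worse(self, params):
        times = np.linspace(0.1, 30.0, 60)
        small = linearization_error(params, 0.0727, 0.01, times)
        large = linearization_error(params, 0.0727, 10.0, times)
        assert large > 10 * small

    def test_monotone_in_dose(self, params):
        times = np.linspace(0.1, 30.0, 30)
        errors = [linearization_error(params, 15.0, d, times)
                  for d in (0.001, 0.01, 0.1, 1.0, 10.0)]
        assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))
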