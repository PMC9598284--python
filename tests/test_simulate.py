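import dataclasses

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from cnspbpk import (
    DosingRegimen,
    EVDSchedule,
    auc_trapezoid,
    build_transfer_matrix,
    dialysate_prediction,
    evd_dose_fraction,
    evd_prediction,
    simulate,
    steady_state,
)
from cnspbpk.simulate import SimulationResult, SteadyStateError

from conftest import rhs_concentrations


class TestSteadyState:
    def test_periodicity(self, sys_params, drug, phys, regimen):
        """Propagating the steady state one dosing interval returns it."""
        x0 = steady_state(sys_params, drug, phys, regimen)
        res = simulate(sys_params, drug, phys, regimen)
        x_tau = res.amounts[-1, :5]
        assert np.linalg.norm(x_tau - x0[:5]) / np.linalg.norm(x0[:5]) < 1e-8

    def test_matches_brute_force_repeated_dosing(self, sys_params, drug, phys, regimen):
        """Independent oracle: iterate the one-interval affine map from zero."""
        M, u = build_transfer_matrix(sys_params, drug, phys)
        n = M.shape[0]
        G_on = np.zeros((n + 1, n + 1))
        G_on[:n, :n] = M
        G_on[:n, n] = regimen.rate * u
        P_on = expm(G_on * regimen.infusion_duration)
        G_off = np.zeros((n + 1, n + 1))
        G_off[:n, :n] = M
        P_off = expm(G_off * (regimen.tau - regimen.infusion_duration))
        z = np.zeros(n + 1)
        z[n] = 1.0
        for _ in range(60):
            z = P_off @ (P_on @ z)
            z[5] = 0.0  # bag emptied each interval
        x0 = steady_state(sys_params, drug, phys, regimen)
        np.testing.assert_allclose(x0[:5], z[:5], rtol=1e-6)

    def test_zero_dose_gives_zero_state(self, sys_params, drug, phys):
        regimen = DosingRegimen(dose=0.0)
        x0 = steady_state(sys_params, drug, phys, regimen)
        np.testing.assert_allclose(x0, 0.0, atol=1e-12)

    def test_no_elimination_reports_non_convergence(self, sys_params, drug, phys, regimen):
        immortal = dataclasses.replace(drug, CL=0.0)
        with pytest.raises(SteadyStateError, match="residual"):
            steady_state(sys_params, immortal, phys, regimen)


class TestSimulate:
    def test_zero_dose_all_zero(self, sys_params, drug, phys):
        res = simulate(sys_params, drug, phys, DosingRegimen(dose=0.0))
        np.testing.assert_allclose(res.amounts, 0.0, atol=1e-12)

    def test_average_blood_concentration_closed_form(
        self, sys_params, drug, phys, regimen
    ):
        """At steady state without a drain, CL * avg(C_B) = dose rate."""
        res = simulate(sys_params, drug, phys, regimen)
        avg = res.auc("blood", 0.0, regimen.tau) / regimen.tau
        assert avg == pytest.approx(regimen.dose / (regimen.tau * drug.CL), rel=1e-9)

    def test_mass_balance_closed_system(self, sys_params, drug, phys, regimen):
        """With clearance and drain zeroed, dosed mass is fully retained."""
        lossless = dataclasses.replace(drug, CL=0.0)
        res = simulate(
            sys_params, lossless, phys, regimen, n_doses=3, t_end=3 * regimen.tau
        )
        total = res.amounts[-1].sum()
        assert total == pytest.approx(3 * regimen.dose, rel=1e-9)

    def test_superposition_in_dose(self, sys_params, drug, phys, regimen):
        res1 = simulate(sys_params, drug, phys, regimen)
        res2 = simulate(
            sys_params, drug, phys, dataclasses.replace(regimen, dose=1000.0)
        )
        np.testing.assert_allclose(res2.amounts, 2.0 * res1.amounts, rtol=1e-10)

    def test_matches_adaptive_ode_solver(self, sys_params, drug, phys, regimen):
        """Matrix-exponential trajectory vs an independent stiff ODE solve."""
        res = simulate(sys_params, drug, phys, regimen, 0.02, grid_step=0.5)
        vols = res.volumes

        def rhs(t, a):
            rate = regimen.rate if t < regimen.infusion_duration else 0.0
            return rhs_concentrations(
                sys_params, drug, phys, 0.02, a[:5] / vols[:5], rate
            ) * np.concatenate([vols[:5], [1.0]])

        sol = solve_ivp(
            rhs,
            (0.0, regimen.tau),
            res.amounts[0],
            t_eval=res.times,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        np.testing.assert_allclose(sol.y.T, res.amounts, rtol=1e-6, atol=1e-9)

    def test_ecf_and_csf_profiles_nearly_superimposable(
        self, sys_params, drug, phys, regimen
    ):
        """High passive permeability makes the two CNS profiles similar."""
        res = simulate(sys_params, drug, phys, regimen)
        ce, cc = res.conc("ecf"), res.conc("csf")
        rel = np.abs(ce - cc) / np.maximum(ce, cc)
        assert np.max(rel) < 0.15

    def test_single_dose_auc_equals_steady_state_interval_auc(
        self, sys_params, drug, phys, regimen
    ):
        """Linear-PK identity: AUC(0-inf) single dose == AUC over tau at SS."""
        ss = simulate(sys_params, drug, phys, regimen)
        single = simulate(sys_params, drug, phys, regimen, n_doses=1, t_end=400.0)
        auc_ss = ss.auc("blood", 0.0, regimen.tau)
        auc_inf = single.auc("blood", 0.0, 400.0)
        assert auc_inf == pytest.approx(auc_ss, rel=1e-3)

    def test_cns_to_blood_auc_ratios_near_unity(self, sys_params, drug, phys, regimen):
        res = simulate(sys_params, drug, phys, regimen)
        blood = res.auc("blood", 0.0, regimen.tau)
        assert 0.85 <= res.auc("ecf", 0.0, regimen.tau) / blood <= 1.0
        assert 0.85 <= res.auc("csf", 0.0, regimen.tau) / blood <= 1.0


@pytest.fixture(scope="module")
def result(sys_params, drug, phys, regimen):
    return simulate(sys_params, drug, phys, regimen, 0.02, extra_times=(1.25, 2.75))


@pytest.fixture(scope="module")
def fine(sys_params, drug, phys, regimen):
    """Spline of a very fine-grid trajectory: independent quadrature oracle."""
    from scipy.interpolate import CubicSpline

    res = simulate(sys_params, drug, phys, regimen, 0.02, grid_step=0.005)
    return {
        "ecf": CubicSpline(res.times, res.conc("ecf")),
        "csf": CubicSpline(res.times, res.conc("csf")),
    }


class TestIntervalPredictions:
    def test_constant_profile_time_average(self):
        t = np.linspace(0.0, 8.0, 161)
        const = SimulationResult(
            times=t,
            amounts=np.full((161, 6), 2.0),
            integrals=np.column_stack([2.0 * t] * 3),
            volumes=np.ones(6),
            regimen=DosingRegimen(),
        )
        assert dialysate_prediction(const, 1.0, 3.0) == pytest.approx(2.0)

    def test_linear_profile_gives_midpoint_value(self):
        t = np.linspace(0.0, 8.0, 161)
        # amount a(t) = t  ->  integral t^2/2; unit volumes
        lin = SimulationResult(
            times=t,
            amounts=np.tile(t[:, None], (1, 6)),
            integrals=np.column_stack([t**2 / 2] * 3),
            volumes=np.ones(6),
            regimen=DosingRegimen(),
        )
        assert dialysate_prediction(lin, 2.0, 5.0) == pytest.approx(3.5)

    def test_dialysate_matches_quadrature_oracle(self, result, fine):
        oracle = fine["ecf"].integrate(1.25, 2.75) / 1.5
        assert dialysate_prediction(result, 1.25, 2.75) == pytest.approx(
            oracle, rel=1e-6
        )

    def test_evd_matches_quadrature_oracle(self, result, fine):
        oracle = 0.02 * fine["csf"].integrate(1.25, 2.75) / 0.03
        assert evd_prediction(result, 1.25, 2.75, 0.02, 0.03) == pytest.approx(
            oracle, rel=1e-6
        )

    def test_evd_consistent_volume_is_time_average(self, result):
        pred = evd_prediction(result, 1.0, 2.0, 0.02, 0.02)
        assert pred == pytest.approx(result.interval_average("csf", 1.0, 2.0))

    def test_evd_zero_flow_flagged_missing(self, result):
        assert np.isnan(evd_prediction(result, 1.0, 2.0, 0.0, 0.02))

    def test_evd_rejects_non_positive_volume(self, result):
        with pytest.raises(ValueError):
            evd_prediction(result, 1.0, 2.0, 0.02, 0.0)

    def test_interval_outside_grid_rejected(self, result):
        with pytest.raises(ValueError, match="outside"):
            dialysate_prediction(result, 7.0, 9.0)


class TestAucTrapezoid:
    def test_constant_and_triangle(self):
        assert auc_trapezoid([0.0, 8.0], [1.0, 1.0]) == pytest.approx(8.0)
        assert auc_trapezoid([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_dense_exponential_decay(self):
        t = np.linspace(0.0, 10.0, 2001)
        c = np.exp(-0.5 * t)
        exact = (1.0 - np.exp(-5.0)) / 0.5
        assert auc_trapezoid(t, c) == pytest.approx(exact, rel=1e-3)

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])


class TestEvdDoseFraction:
    def test_zero_flow_zero_fraction(self, sys_params, drug, phys, regimen):
        res = simulate(sys_params, drug, phys, regimen)
        assert evd_dose_fraction(res, 0.0) == 0.0

    def test_mid_range_flow_within_observed_bound(
        self, sys_params, drug, phys, regimen
    ):
        """At the fitted parameters the bag captures at most 0.4% of a dose."""
        res = simulate(sys_params, drug, phys, regimen, 0.02)
        assert 0.0 < evd_dose_fraction(res, 0.02) <= 0.4

    def test_state_based_route_agrees(self, sys_params, drug, phys, regimen):
        res = simulate(sys_params, drug, phys, regimen, 0.03)
        a = evd_dose_fraction(res, 0.03)
        b = evd_dose_fraction(res, 0.03, from_state=True)
        assert a == pytest.approx(b, rel=1e-8)

    def test_evd_schedule_breaks_are_respected(self, sys_params, drug, phys, regimen):
        """Piecewise drain flows accumulate segment by segment."""
        sched = EVDSchedule(
            [(0.0, 4.0, 0.01, 0.04), (4.0, 8.0, 0.03, 0.12)]
        )
        res = simulate(sys_params, drug, phys, regimen, sched)
        manual = 0.01 * res.auc("csf", 0.0, 4.0) + 0.03 * res.auc("csf", 4.0, 8.0)
        assert res.amounts[-1, 5] == pytest.approx(manual, rel=1e-8)
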