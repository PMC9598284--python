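import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from cnspbpk import (
    CohortDesign,
    FitConfig,
    bootstrap_ci,
    cv_percent_from_omega,
    fit_population,
    fold_error,
    generate_cohort,
    individual_loglik,
    laplace_marginal,
    omega_from_cv_percent,
    patients_from_frame,
)

SIGMAS = {
    "sigma_prop_plasma": 0.144,
    "sigma_add_plasma": 1.18,
    "sigma_prop_ecf": 0.228,
    "sigma_prop_csf": 0.282,
}


def quiet_truth(truth):
    return dataclasses.replace(
        truth,
        omega_cl=1e-12,
        sigma_prop_plasma=0.0,
        sigma_add_plasma=0.0,
        sigma_prop_ecf=0.0,
        sigma_prop_csf=0.0,
    )


@pytest.fixture(scope="module")
def noiseless_patients(design, truth, sys_params):
    frame = generate_cohort(design, quiet_truth(truth), sys_params, seed=21)
    return patients_from_frame(frame)


@pytest.fixture(scope="module")
def noisy_patients(design, truth, sys_params):
    frame = generate_cohort(design, truth, sys_params, seed=8)
    return patients_from_frame(frame)


class TestCvConversion:
    def test_roundtrip(self):
        for cv in (5.0, 35.2, 80.0):
            assert cv_percent_from_omega(omega_from_cv_percent(cv)) == pytest.approx(cv)


class TestIndividualLoglik:
    def test_zero_residuals_analytic_value(self, noiseless_patients, sys_params, truth):
        """With data equal to predictions the loglik is -sum(0.5*log(2*pi*var))."""
        p = noiseless_patients[0]
        ll = individual_loglik(p, sys_params, truth.drug, 0.0, SIGMAS)
        expected = 0.0
        for o in p.observations:
            if o.stream == "plasma_unbound":
                var = (SIGMAS["sigma_prop_plasma"] * o.value) ** 2 + SIGMAS[
                    "sigma_add_plasma"
                ] ** 2
            elif o.stream == "dialysate":
                var = (SIGMAS["sigma_prop_ecf"] * o.value) ** 2
            else:
                var = (SIGMAS["sigma_prop_csf"] * o.value) ** 2
            expected -= 0.5 * math.log(2.0 * math.pi * var)
        assert ll == pytest.approx(expected, rel=1e-6)

    def test_doubling_additive_sigma_costs_log2_per_plasma_point(
        self, noiseless_patients, sys_params, truth
    ):
        p = noiseless_patients[0]
        add_only = {**SIGMAS, "sigma_prop_plasma": 0.0}
        doubled = {**add_only, "sigma_add_plasma": 2.0 * add_only["sigma_add_plasma"]}
        ll1 = individual_loglik(p, sys_params, truth.drug, 0.0, add_only)
        ll2 = individual_loglik(p, sys_params, truth.drug, 0.0, doubled)
        n_plasma = len(p.stream("plasma_unbound"))
        assert ll1 - ll2 == pytest.approx(n_plasma * math.log(2.0), rel=1e-9)

    def test_eta_shifts_clearance(self, noisy_patients, sys_params, truth):
        p = noisy_patients[0]
        ll0 = individual_loglik(p, sys_params, truth.drug, 0.0, SIGMAS)
        # same clearance reached via eta or via the population value
        bumped = dataclasses.replace(truth.drug, CL=truth.drug.CL * math.exp(0.3))
        ll_eta = individual_loglik(p, sys_params, truth.drug, 0.3, SIGMAS)
        ll_cl = individual_loglik(p, sys_params, bumped, 0.0, SIGMAS)
        assert ll_eta == pytest.approx(ll_cl, rel=1e-10)
        assert ll_eta != pytest.approx(ll0, rel=1e-6)


class TestLaplaceMarginal:
    @pytest.mark.parametrize("subject_idx", [0, 5])
    def test_matches_quadrature_oracle(
        self, noisy_patients, sys_params, truth, subject_idx
    ):
        """Brute-force quadrature over eta vs the Laplace approximation."""
        p = noisy_patients[subject_idx]
        omega = 0.342

        def g(eta):
            return individual_loglik(
                p, sys_params, truth.drug, eta, SIGMAS
            ) + norm.logpdf(eta, scale=omega)

        g0 = g(0.0)
        integral = quad(lambda e: math.exp(g(e) - g0), -2.5, 2.5, limit=120)[0]
        oracle = g0 + math.log(integral)
        lap = laplace_marginal(p, sys_params, truth.drug, omega, SIGMAS)
        assert lap == pytest.approx(oracle, rel=0.005)


class TestFitPopulation:
    def test_requires_two_subjects(self, noisy_patients, sys_params, truth):
        with pytest.raises(ValueError, match="at least 2"):
            fit_population(noisy_patients[:1], sys_params, truth.drug)

    def test_noise_free_data_recovers_generating_parameters(
        self, noiseless_patients, sys_params, truth
    ):
        """Zero-noise identifiability: CL and Kp come back to <0.5%."""
        cfg = FitConfig(
            n_starts=1,
            fix={
                "omega_cl": 1e-3,
                "sigma_prop_plasma": 0.05,
                "sigma_add_plasma": 0.05,
                "sigma_prop_ecf": 0.05,
                "sigma_prop_csf": 0.05,
            },
        )
        fit = fit_population(noiseless_patients, sys_params, truth.drug, cfg)
        assert fit.theta["CL"] == pytest.approx(truth.drug.CL, rel=5e-3)
        assert fit.theta["Kp"] == pytest.approx(truth.drug.Kp, rel=5e-3)
        assert fit.fixed["fd"] == 0.86
        assert fit.fixed["PS_ECF"] == 6.4
        assert fit.fixed["PS_CSF"] == 3.2

    def test_objective_trace_monotone_on_accepted_steps(
        self, noisy_patients, sys_params, truth
    ):
        fit = fit_population(
            noisy_patients, sys_params, truth.drug, FitConfig(n_starts=1, maxiter=400)
        )
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) <= 0)

    def test_estimate_ps_mode_recovers_barrier_ratio(self, sys_params, truth):
        """Generated with a low (identifiable) PS at ratio 2:1, the
        estimate_PS mode recovers the ratio in the median over replicate
        cohorts (single replicates of 8 subjects are noisy)."""
        low_drug = dataclasses.replace(truth.drug, PS_ECF=0.5, PS_CSF=0.25)
        low_truth = dataclasses.replace(truth, drug=low_drug)
        ratios = []
        for seed in range(30, 35):
            frame = generate_cohort(CohortDesign(), low_truth, sys_params, seed=seed)
            pats = patients_from_frame(frame)
            cfg = FitConfig(
                estimate_ps=True,
                n_starts=2,
                fix={**SIGMAS},
                start={"PS_ECF": 1.0, "PS_CSF": 1.0},
            )
            fit = fit_population(pats, sys_params, truth.drug, cfg)
            ratios.append(fit.theta["PS_ECF"] / fit.theta["PS_CSF"])
        assert np.median(ratios) == pytest.approx(2.0, rel=0.3)


@pytest.fixture(scope="module")
def small_fit(noisy_patients, sys_params, truth):
    cfg = FitConfig(n_starts=1, maxiter=600)
    return cfg, fit_population(noisy_patients, sys_params, truth.drug, cfg)


class TestBootstrap:
    def test_refuses_single_subject(self, noisy_patients, sys_params, truth, small_fit):
        cfg, fit = small_fit
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(noisy_patients[:1], fit, sys_params, truth.drug, cfg)

    def test_seeded_run_reproducible(self, noisy_patients, sys_params, truth, small_fit):
        cfg, fit = small_fit
        kwargs = dict(n_boot=3, seed=77)
        ci1 = bootstrap_ci(noisy_patients, fit, sys_params, truth.drug, cfg, **kwargs)
        ci2 = bootstrap_ci(noisy_patients, fit, sys_params, truth.drug, cfg, **kwargs)
        assert ci1 == ci2
        lo, hi = ci1["CL"]
        assert lo <= hi


class TestFoldError:
    def test_identical_aucs(self):
        assert fold_error([10.0, 20.0], [10.0, 20.0]) == pytest.approx(1.0)

    def test_uniform_twofold(self):
        assert fold_error([2.0, 4.0, 8.0], [1.0, 2.0, 4.0]) == pytest.approx(2.0)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            fold_error([1.0, 0.0], [1.0, 1.0])
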