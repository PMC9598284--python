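"""Seeded synthetic cohorts reproducing the neuro-ICU study design.

The emulated design: brain-injured patients on 500 mg q8h 30-min infusions
sampled at steady state over one dosing interval; half the cohort carries a
microdialysis probe (brain ECF, interval fractions), the other half an
external ventricular drain (CSF collected into a bag, interval fractions
with per-interval drain flow); all subjects contribute 7-13 plasma samples.
CNS fractions are collected at 0.5-h intervals early on and 1-h intervals
for the rest of the 8-h window.  Between-subject variability acts
log-normally on clearance and residual noise follows the fitted error
model (proportional + additive for plasma, proportional for the CNS
streams).  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ObservationRecord, PatientRecord, patients_to_frame
from .estimate import omega_from_cv_percent
from .parameters import (
    DosingRegimen,
    DrugParameters,
    EVDSchedule,
    SystemParameters,
    derive_patient_physiology,
    scaled_ps,
)
from .permeability import ps_csf_from_ps_ecf
from .simulate import dialysate_prediction, evd_prediction, simulate


@dataclass(frozen=True)
class CohortDesign:
    """Study design of the synthetic cohort (defaults = emulated study)."""

    n_microdialysis: int = 4
    n_evd: int = 4
    dose: float = 500.0
    tau: float = 8.0
    infusion_duration: float = 0.5
    n_plasma_range: tuple[int, int] = (7, 13)
    cns_fine_interval: float = 0.5
    cns_fine_until: float = 3.0
    cns_coarse_interval: float = 1.0
    cns_end: float = 8.0
    q_evd_range: tuple[float, float] = (0.001, 0.04)
    recovery_range: tuple[float, float] = (0.4, 0.9)
    weight_range: tuple[float, float] = (75.0, 115.0)
    weights: tuple[float, ...] | None = None  # fixed list overrides the range
    evd_volume_jitter: float = 0.0  # relative jitter on V_EVD vs Q_EVD * dt

    def __post_init__(self) -> None:
        if self.n_microdialysis < 0 or self.n_evd < 0:
            raise ValueError("subject counts must be non-negative")
        if not 0 < self.infusion_duration <= self.tau:
            raise ValueError("impossible design: infusion duration must lie in (0, tau]")
        lo, hi = self.n_plasma_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid plasma sample count range")

    def cns_intervals(self) -> list[tuple[float, float]]:
        edges = list(
            np.arange(0.0, self.cns_fine_until + 1e-9, self.cns_fine_interval)
        ) + list(
            np.arange(
                self.cns_fine_until + self.cns_coarse_interval,
                self.cns_end + 1e-9,
                self.cns_coarse_interval,
            )
        )
        return list(zip(edges[:-1], edges[1:]))


#: candidate plasma sampling times (h after dose), thinned per subject
PLASMA_TIMES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass(frozen=True)
class PopulationTruth:
    """Generating (true) population parameters; defaults = fitted values."""

    drug: DrugParameters = field(default_factory=DrugParameters)
    omega_cl: float = omega_from_cv_percent(35.2)
    sigma_prop_plasma: float = 0.144
    sigma_add_plasma: float = 1.18
    sigma_prop_ecf: float = 0.228
    sigma_prop_csf: float = 0.282

    def sigmas(self) -> dict:
        return {
            "sigma_prop_plasma": self.sigma_prop_plasma,
            "sigma_add_plasma": self.sigma_add_plasma,
            "sigma_prop_ecf": self.sigma_prop_ecf,
            "sigma_prop_csf": self.sigma_prop_csf,
        }


def draw_individual_cl(
    truth: PopulationTruth, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Individual clearances CL_i = CL * exp(eta_i), eta_i ~ N(0, omega^2)."""
    return truth.drug.CL * np.exp(rng.normal(0.0, truth.omega_cl, size=n))


def _positive_noise(
    rng: np.random.Generator, pred: float, sigma_prop: float, sigma_add: float = 0.0
) -> float:
    """Proportional(+additive) residual draw, redrawn until positive."""
    if sigma_prop == 0.0 and sigma_add == 0.0:
        return pred
    for _ in range(1000):
        value = pred * (1.0 + sigma_prop * rng.normal()) + sigma_add * rng.normal()
        if value > 0:
            return value
    raise RuntimeError("could not draw a positive observation (noise too large)")


def generate_cohort(
    design: CohortDesign = CohortDesign(),
    truth: PopulationTruth = PopulationTruth(),
    sys: SystemParameters = SystemParameters(),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a synthetic cohort as a long-format dataset.

    Subjects 1..n_microdialysis carry the dialysate stream, the rest the
    EVD stream; every subject contributes plasma samples.  Identical seeds
    give identical frames.
    """
    rng = np.random.default_rng(seed)
    n_total = design.n_microdialysis + design.n_evd
    regimen = DosingRegimen(
        dose=design.dose, infusion_duration=design.infusion_duration, tau=design.tau
    )
    intervals = design.cns_intervals()
    patients: list[PatientRecord] = []

    for i in range(n_total):
        sid = f"S{i + 1:03d}"
        is_md = i < design.n_microdialysis
        if design.weights is not None:
            wt = float(design.weights[i % len(design.weights)])
        else:
            wt = float(rng.uniform(*design.weight_range))
        eta = rng.normal(0.0, truth.omega_cl)
        drug_i = dataclasses.replace(truth.drug, CL=truth.drug.CL * np.exp(eta))
        phys = derive_patient_physiology(wt, sys, drug_i.fd)

        n_plasma = int(rng.integers(design.n_plasma_range[0], design.n_plasma_range[1] + 1))
        n_plasma = min(n_plasma, len(PLASMA_TIMES))
        plasma_times = np.sort(
            rng.choice(PLASMA_TIMES, size=n_plasma, replace=False)
        )

        if is_md:
            recovery = float(rng.uniform(*design.recovery_range))
            evd = None
            schedule = None
        else:
            recovery = None
            q = rng.uniform(*design.q_evd_range, size=len(intervals))
            v = np.array(
                [
                    qk * (t2 - t1) * (1.0 + design.evd_volume_jitter * rng.uniform(-1, 1))
                    for qk, (t1, t2) in zip(q, intervals)
                ]
            )
            schedule = list(zip(q, v))
            evd = EVDSchedule(
                [(t1, t2, qk, vk) for (t1, t2), qk, vk in zip(intervals, q, v)]
            )

        extra = tuple(plasma_times) + tuple(t for iv in intervals for t in iv)
        res = simulate(sys, drug_i, phys, regimen, evd, extra_times=extra)

        obs: list[ObservationRecord] = []
        for t in plasma_times:
            pred = float(np.interp(t, res.times, res.conc("blood")))
            obs.append(
                ObservationRecord(
                    stream="plasma_unbound",
                    time=float(t),
                    value=_positive_noise(
                        rng, pred, truth.sigma_prop_plasma, truth.sigma_add_plasma
                    ),
                )
            )
        if is_md:
            for t1, t2 in intervals:
                pred = dialysate_prediction(res, t1, t2)
                obs.append(
                    ObservationRecord(
                        stream="dialysate",
                        t1=t1,
                        t2=t2,
                        value=_positive_noise(rng, pred, truth.sigma_prop_ecf),
                        recovery=recovery,
                    )
                )
        else:
            for (t1, t2), (qk, vk) in zip(intervals, schedule):
                pred = evd_prediction(res, t1, t2, qk, vk)
                obs.append(
                    ObservationRecord(
                        stream="evd",
                        t1=t1,
                        t2=t2,
                        value=_positive_noise(rng, pred, truth.sigma_prop_csf),
                        q_evd=float(qk),
                        v_evd=float(vk),
                    )
                )
        patients.append(
            PatientRecord(subject_id=sid, weight=wt, regimen=regimen, observations=obs)
        )
    return patients_to_frame(patients)


def generate_low_ps_scenario(
    base: DrugParameters,
    ps_scale: float | None = None,
    ps_ecf: float | None = None,
    mw: float = 455.0,
    logp: float = -1.5,
) -> DrugParameters:
    """Hypothetical low-permeability drug scenario.

    Either rescales the barrier clearances of ``base`` by ``ps_scale`` or
    sets ``PS_ECF`` outright (with the BCSFB clearance from the halving
    rule).  The molecular weight and lipophilicity are carried as metadata
    of the scenario only; no permeability is predicted from them.
    """
    if (ps_scale is None) == (ps_ecf is None):
        raise ValueError("give exactly one of ps_scale or ps_ecf")
    if ps_ecf is not None:
        return dataclasses.replace(
            base, PS_ECF=ps_ecf, PS_CSF=ps_csf_from_ps_ecf(ps_ecf), MW=mw, logP=logp
        )
    if ps_scale == 1.0:
        return base
    return dataclasses.replace(scaled_ps(base, ps_scale), MW=mw, logP=logp)
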