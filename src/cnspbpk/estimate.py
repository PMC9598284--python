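"""Population (nonlinear mixed-effects) estimation for the CNS PBPK model.

Plasma, microdialysate and EVD observations from all subjects are fitted
simultaneously.  Between-subject variability is a log-normal random effect
on clearance (``CL_i = CL * exp(eta_i)``, ``eta_i ~ N(0, omega^2)``);
residual error is proportional-plus-additive for plasma and proportional
for the two CNS streams.  The marginal likelihood is approximated by the
Laplace method with per-subject mode finding, a standard conditional-
estimation approximation; parameter uncertainty comes from a nonparametric
subject-level bootstrap.

The fixing strategy mirrors the study analysis: the tissue flow fraction
``fd`` is fixed at its maximum allowed value and the barrier clearances
``PS_ECF``/``PS_CSF`` are fixed to their predicted values unless the
``estimate_ps`` mode is requested.

Implementation note: predictions for many (subject, clearance) cases are
evaluated in one batched matrix-exponential call over all piecewise-
constant segments, which keeps repeated-fit experiments (bootstrap,
parameter recovery) fast.  The batched engine is cross-checked against the
reference :func:`cnspbpk.simulate.simulate` path in the test suite.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .data import PatientRecord
from .model import effective_sink_flow
from .parameters import (
    DrugParameters,
    SystemParameters,
    derive_patient_physiology,
)

_LOG2PI = math.log(2.0 * math.pi)

# hot-path augmented state: [A_blood, A_tissue, A_vasc, A_ecf, A_csf, J_ecf, J_csf, s]
_NA = 8
_JE, _JC, _S = 5, 6, 7

PARAM_NAMES = (
    "CL",
    "Kp",
    "omega_cl",
    "sigma_prop_plasma",
    "sigma_add_plasma",
    "sigma_prop_ecf",
    "sigma_prop_csf",
)
PS_NAMES = ("PS_ECF", "PS_CSF")

_STREAM_CODE = {"plasma_unbound": 0, "dialysate": 1, "evd": 2}

# Pade-13 coefficients for the matrix exponential
_PADE13 = (
    64764752532480000.0, 32382376266240000.0, 7771770303897600.0,
    1187353796428800.0, 129060195264000.0, 10559470521600.0, 670442572800.0,
    33522128640.0, 1323241920.0, 40840800.0, 960960.0, 16380.0, 182.0, 1.0,
)
_THETA13 = 4.25  # scaling threshold for degree-13 Pade


def expm_batch(A: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of small matrices, fully vectorized.

    Scaling-and-squaring with a degree-13 Pade approximant, applied to the
    whole stack at once (SciPy's ``expm`` iterates over the stack in
    Python, which dominates run time for many small matrices).  Scaling is
    chosen per matrix; squaring steps are masked so each matrix is squared
    exactly as often as its norm requires.
    """
    A = np.asarray(A, dtype=float)
    stack = A.shape[:-2]
    n = A.shape[-1]
    A = A.reshape(-1, n, n)
    norms = np.abs(A).sum(axis=-1).max(axis=-1)
    with np.errstate(divide="ignore"):
        s = np.ceil(np.log2(norms / _THETA13))
    s = np.where(np.isfinite(s), np.maximum(s, 0.0), 0.0).astype(int)
    As = A / (2.0 ** s)[:, None, None]

    eye = np.broadcast_to(np.eye(n), As.shape)
    b = _PADE13
    A2 = As @ As
    A4 = A2 @ A2
    A6 = A2 @ A4
    U = As @ (
        A6 @ (b[13] * A6 + b[11] * A4 + b[9] * A2)
        + b[7] * A6 + b[5] * A4 + b[3] * A2 + b[1] * eye
    )
    V = (
        A6 @ (b[12] * A6 + b[10] * A4 + b[8] * A2)
        + b[6] * A6 + b[4] * A4 + b[2] * A2 + b[0] * eye
    )
    R = np.linalg.solve(V - U, V + U)
    for i in range(int(s.max()) if s.size else 0):
        mask = s > i
        R[mask] = R[mask] @ R[mask]
    return R.reshape(*stack, n, n)


def cv_percent_from_omega(omega: float) -> float:
    """Log-normal SD -> coefficient of variation in percent."""
    return 100.0 * math.sqrt(math.exp(omega**2) - 1.0)


def omega_from_cv_percent(cv: float) -> float:
    """Coefficient of variation in percent -> log-normal SD."""
    return math.sqrt(math.log(1.0 + (cv / 100.0) ** 2))


@dataclass
class FitConfig:
    """Settings for :func:`fit_population`."""

    estimate_ps: bool = False
    apply_recovery: bool = False  # divide raw dialysate DV by probe recovery
    fix: dict = field(default_factory=dict)  # parameter name -> fixed value
    start: dict = field(default_factory=dict)  # overrides for starting values
    n_starts: int = 3
    maxiter: int = 4000
    xatol: float = 5e-4
    fatol: float = 1e-4
    inner_iters: int = 10
    tau: float = 8.0
    seed: int = 0


@dataclass
class PopulationFit:
    """Result of a population fit."""

    theta: dict
    fixed: dict
    omega_cl: float
    sigmas: dict
    objective: float
    converged: bool
    n_subjects: int
    etas: dict
    trace: list = field(default_factory=list)
    ci: dict | None = None

    @property
    def cv_percent(self) -> float:
        return cv_percent_from_omega(self.omega_cl)

    def drug(self, base: DrugParameters = DrugParameters()) -> DrugParameters:
        """Drug parameter set at the population estimates."""
        kwargs = {k: v for k, v in {**self.fixed, **self.theta}.items()
                  if k in {"CL", "Kp", "PS_ECF", "PS_CSF", "fd"}}
        return dataclasses.replace(base, **kwargs)


class PredictionEngine:
    """Batched steady-state observation predictions for a cohort.

    Precomputes, per subject, the piecewise-constant segment structure of
    one dosing interval (infusion on/off, EVD collection intervals, all
    observation times as exact breakpoints).  ``predict(cl)`` then returns
    model predictions for every observation for arbitrarily many clearance
    values per subject in a single vectorized pass.
    """

    def __init__(
        self,
        patients: list[PatientRecord],
        sys: SystemParameters,
        base_drug: DrugParameters,
        apply_recovery: bool = False,
    ):
        self.patients = patients
        self.sys = sys
        self.base_drug = base_drug
        self.n_sub = len(patients)

        seg_dt, seg_qevd, seg_rate = [], [], []
        self._vt = np.empty(self.n_sub)
        self._nseg = np.empty(self.n_sub, dtype=int)
        pt_s, pt_k, pt_pos = [], [], []
        iv_s, iv_k1, iv_k2, iv_state, iv_coef, iv_pos = [], [], [], [], [], []
        dv, stream_code, subj_of_obs = [], [], []
        pos = 0

        for s, p in enumerate(patients):
            phys = derive_patient_physiology(p.weight, sys, base_drug.fd)
            self._vt[s] = phys.V_tissue
            tau = p.regimen.tau
            bp = {0.0, p.regimen.infusion_duration, tau}
            for o in p.observations:
                if o.stream == "plasma_unbound":
                    if not 0.0 <= o.time <= tau + 1e-9:
                        raise ValueError(
                            f"subject {p.subject_id}: observation time {o.time} "
                            "outside the dosing interval"
                        )
                    bp.add(float(o.time))
                else:
                    if not (0.0 <= o.t1 and o.t2 <= tau + 1e-9):
                        raise ValueError(
                            f"subject {p.subject_id}: interval [{o.t1}, {o.t2}] "
                            "outside the dosing interval"
                        )
                    bp.update((float(o.t1), float(o.t2)))
            sched = p.evd_schedule()
            if sched is not None:
                bp.update(b for b in sched.boundaries() if 0.0 <= b <= tau)
            bp = np.array(sorted(bp))
            mids = 0.5 * (bp[:-1] + bp[1:])
            seg_dt.append(np.diff(bp))
            seg_qevd.append(
                np.array([sched.flow_at(m) if sched is not None else 0.0 for m in mids])
            )
            seg_rate.append(
                np.where(mids < p.regimen.infusion_duration, p.regimen.rate, 0.0)
            )
            self._nseg[s] = len(mids)

            def _kof(t: float) -> int:
                k = int(np.argmin(np.abs(bp - t)))
                if abs(bp[k] - t) > 1e-9:  # pragma: no cover - guarded above
                    raise ValueError(f"time {t} not aligned with breakpoints")
                return k

            phys_vols = {"ecf": sys.V_ECF, "csf": sys.V_CSF}
            for o in p.observations:
                value = o.value
                if o.stream == "dialysate" and apply_recovery:
                    if not o.recovery:
                        raise ValueError(
                            f"subject {p.subject_id}: recovery correction requested "
                            "but no probe recovery recorded"
                        )
                    value = value / o.recovery
                dv.append(value)
                stream_code.append(_STREAM_CODE[o.stream])
                subj_of_obs.append(s)
                if o.stream == "plasma_unbound":
                    pt_s.append(s)
                    pt_k.append(_kof(o.time))
                    pt_pos.append(pos)
                else:
                    iv_s.append(s)
                    iv_k1.append(_kof(o.t1))
                    iv_k2.append(_kof(o.t2))
                    if o.stream == "dialysate":
                        iv_state.append(_JE)
                        iv_coef.append(1.0 / (phys_vols["ecf"] * (o.t2 - o.t1)))
                    else:
                        iv_state.append(_JC)
                        iv_coef.append(o.q_evd / (phys_vols["csf"] * o.v_evd))
                    iv_pos.append(pos)
                pos += 1

        self.n_obs = pos
        self._rmax = int(self._nseg.max())
        S, R = self.n_sub, self._rmax
        self._dt = np.zeros((S, R))
        self._qevd = np.zeros((S, R))
        self._qsink = np.full((S, R), sys.Q_sink_physio)
        self._rate = np.zeros((S, R))
        for s in range(S):
            r = self._nseg[s]
            self._dt[s, :r] = seg_dt[s]
            self._qevd[s, :r] = seg_qevd[s]
            self._qsink[s, :r] = [
                effective_sink_flow(q, sys.Q_sink_physio) for q in seg_qevd[s]
            ]
            self._rate[s, :r] = seg_rate[s]

        self._pt = (np.array(pt_s, int), np.array(pt_k, int), np.array(pt_pos, int))
        self._iv = (
            np.array(iv_s, int),
            np.array(iv_k1, int),
            np.array(iv_k2, int),
            np.array(iv_state, int),
            np.array(iv_coef, float),
            np.array(iv_pos, int),
        )
        self.dv = np.array(dv)
        self.stream_code = np.array(stream_code, int)
        self.subj_of_obs = np.array(subj_of_obs, int)
        # observations were appended subject by subject -> contiguous blocks
        self._obs_starts = np.searchsorted(self.subj_of_obs, np.arange(S))

    # -- core batched prediction ------------------------------------------

    def predict(
        self,
        cl: np.ndarray,
        kp: float | None = None,
        ps_ecf: float | None = None,
        ps_csf: float | None = None,
    ) -> np.ndarray:
        """Predictions (P, n_obs) for clearance values ``cl`` of shape (P, S)."""
        sys, drug = self.sys, self.base_drug
        kp = drug.Kp if kp is None else kp
        ps_e = drug.PS_ECF if ps_ecf is None else ps_ecf
        ps_c = drug.PS_CSF if ps_csf is None else ps_csf
        cl = np.atleast_2d(np.asarray(cl, float))
        P, S = cl.shape
        R = self._rmax
        vb, vv, ve, vc = sys.V_blood, sys.V_brain_vasc, sys.V_ECF, sys.V_CSF
        fdco = drug.fd * sys.CO
        qb, qbulk = sys.Q_brain, sys.Q_bulk

        G = np.zeros((P, S, R, _NA, _NA))
        G[..., 0, 0] = -(fdco + qb + cl[:, :, None]) / vb
        G[..., 1, 0] = fdco / vb
        G[..., 2, 0] = qb / vb
        G[..., 0, 1] = fdco / (kp * self._vt[None, :, None])
        G[..., 1, 1] = -G[..., 0, 1]
        G[..., 0, 2] = qb / vv
        G[..., 3, 2] = ps_e / vv
        G[..., 4, 2] = ps_c / vv
        G[..., 2, 2] = -(qb + ps_e + ps_c) / vv
        G[..., 2, 3] = ps_e / ve
        G[..., 4, 3] = qbulk / ve
        G[..., 3, 3] = -(ps_e + qbulk) / ve
        G[..., 2, 4] = (ps_c + self._qsink[None, :, :]) / vc
        G[..., 4, 4] = -(ps_c + self._qsink + self._qevd)[None, :, :] / vc
        G[..., _JE, 3] = 1.0
        G[..., _JC, 4] = 1.0
        G[..., 0, _S] = self._rate[None, :, :]
        G *= self._dt[None, :, :, None, None]

        props = expm_batch(G)

        cums = np.empty((P, S, R + 1, _NA, _NA))
        cums[:, :, 0] = np.eye(_NA)
        for k in range(R):
            cums[:, :, k + 1] = np.matmul(props[:, :, k], cums[:, :, k])

        end = cums[:, np.arange(S), self._nseg]  # (P, S, 8, 8)
        A5 = end[..., :5, :5]
        b5 = end[..., :5, _S]
        x0 = np.linalg.solve(np.eye(5)[None, None] - A5, b5[..., None])[..., 0]

        z0 = np.zeros((P, S, _NA))
        z0[..., :5] = x0
        z0[..., _S] = 1.0
        Z = np.einsum("psrij,psj->psri", cums, z0)

        preds = np.empty((P, self.n_obs))
        pt_s, pt_k, pt_pos = self._pt
        if pt_pos.size:
            preds[:, pt_pos] = Z[:, pt_s, pt_k, 0] / vb
        iv_s, iv_k1, iv_k2, iv_state, iv_coef, iv_pos = self._iv
        if iv_pos.size:
            preds[:, iv_pos] = (
                Z[:, iv_s, iv_k2, iv_state] - Z[:, iv_s, iv_k1, iv_state]
            ) * iv_coef
        return preds

    def loglik(self, preds: np.ndarray, sigmas: dict) -> np.ndarray:
        """Per-subject Gaussian log-likelihoods (P, S) for given predictions."""
        sp = np.array(
            [
                sigmas["sigma_prop_plasma"],
                sigmas["sigma_prop_ecf"],
                sigmas["sigma_prop_csf"],
            ]
        )[self.stream_code]
        var = (sp * preds) ** 2
        var[:, self.stream_code == 0] += sigmas["sigma_add_plasma"] ** 2
        var = np.maximum(var, 1e-12)
        ll_obs = -0.5 * (_LOG2PI + np.log(var) + (self.dv - preds) ** 2 / var)
        return np.add.reduceat(ll_obs, self._obs_starts, axis=1)

    # -- Laplace marginal --------------------------------------------------

    def laplace_m2ll(
        self,
        cl_pop: float,
        kp: float,
        omega: float,
        sigmas: dict,
        ps_ecf: float | None = None,
        ps_csf: float | None = None,
        eta0: np.ndarray | None = None,
        inner_iters: int = 10,
    ) -> tuple[float, np.ndarray]:
        """-2 log marginal likelihood via the Laplace approximation.

        The per-subject posterior modes of ``eta`` are found by a
        safeguarded Newton iteration run in lockstep across subjects, with
        all model evaluations batched; the curvature from the final central
        difference supplies the Laplace correction.
        """
        S = self.n_sub
        eta = np.zeros(S) if eta0 is None else eta0.copy()
        w2 = max(omega, 1e-6) ** 2
        h = 1e-3
        offs = np.array([-h, 0.0, h])
        g3 = None
        for _ in range(inner_iters):
            etas3 = eta[None, :] + offs[:, None]
            preds = self.predict(cl_pop * np.exp(etas3), kp, ps_ecf, ps_csf)
            if not np.all(np.isfinite(preds)):
                return np.inf, eta
            ll3 = self.loglik(preds, sigmas)
            g3 = ll3 - etas3**2 / (2 * w2) - 0.5 * math.log(2 * math.pi * w2)
            g1 = (g3[2] - g3[0]) / (2 * h)
            g2 = (g3[2] - 2 * g3[1] + g3[0]) / h**2
            step = np.where(g2 < -1e-9, -g1 / g2, np.sign(g1) * 0.2)
            step = np.clip(step, -1.0, 1.0)
            eta = np.clip(eta + step, -6.0, 6.0)
            if np.max(np.abs(step)) < 1e-6:
                break
        etas3 = eta[None, :] + offs[:, None]
        preds = self.predict(cl_pop * np.exp(etas3), kp, ps_ecf, ps_csf)
        if not np.all(np.isfinite(preds)):
            return np.inf, eta
        ll3 = self.loglik(preds, sigmas)
        g3 = ll3 - etas3**2 / (2 * w2) - 0.5 * math.log(2 * math.pi * w2)
        g2 = (g3[2] - 2 * g3[1] + g3[0]) / h**2
        g2 = np.where(g2 < -1e-9, g2, -1.0 / w2)
        lmarg = g3[1] + 0.5 * _LOG2PI - 0.5 * np.log(-g2)
        return float(-2.0 * lmarg.sum()), eta


def individual_loglik(
    patient: PatientRecord,
    sys: SystemParameters,
    drug: DrugParameters,
    eta_cl: float,
    sigmas: dict,
    apply_recovery: bool = False,
) -> float:
    """Conditional log-likelihood of one subject's data given ``eta_cl``.

    Uses ``CL_i = drug.CL * exp(eta_cl)``; the residual variance is
    ``sigma_prop^2 * pred^2`` for the CNS streams with an additional
    ``sigma_add^2`` for plasma.
    """
    eng = PredictionEngine([patient], sys, drug, apply_recovery=apply_recovery)
    preds = eng.predict(np.array([[drug.CL * math.exp(eta_cl)]]))
    bad = ~np.isfinite(preds[0])
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite prediction for subject {patient.subject_id}, "
            f"observation #{idx} ({patient.observations[idx].stream})"
        )
    return float(eng.loglik(preds, sigmas)[0, 0])


def laplace_marginal(
    patient: PatientRecord,
    sys: SystemParameters,
    drug: DrugParameters,
    omega_cl: float,
    sigmas: dict,
    apply_recovery: bool = False,
) -> float:
    """Laplace-approximated log marginal likelihood for one subject."""
    eng = PredictionEngine([patient], sys, drug, apply_recovery=apply_recovery)
    m2ll, _ = eng.laplace_m2ll(drug.CL, drug.Kp, omega_cl, sigmas)
    return -0.5 * m2ll


def _default_start(patients: list[PatientRecord]) -> dict:
    plasma = [
        (o.value, p.regimen.dose / p.regimen.tau)
        for p in patients
        for o in p.stream("plasma_unbound")
    ]
    if plasma:
        cl0 = float(np.median([rate / v for v, rate in plasma]))
        cl0 = min(max(cl0, 0.5), 100.0)
    else:
        cl0 = 5.0
    return {
        "CL": cl0,
        "Kp": 1.0,
        "omega_cl": 0.3,
        "sigma_prop_plasma": 0.2,
        "sigma_add_plasma": 1.0,
        "sigma_prop_ecf": 0.2,
        "sigma_prop_csf": 0.2,
        "PS_ECF": None,
        "PS_CSF": None,
    }


def fit_population(
    patients: list[PatientRecord],
    sys: SystemParameters = SystemParameters(),
    base_drug: DrugParameters = DrugParameters(),
    config: FitConfig = FitConfig(),
) -> PopulationFit:
    """Maximize the Laplace marginal likelihood over the free parameters.

    Free parameters are ``CL``, ``Kp``, the IIV SD ``omega_cl`` and the
    four residual SDs (plus ``PS_ECF``/``PS_CSF`` in ``estimate_ps`` mode);
    any entry of ``config.fix`` is held at the given value.  ``fd`` and the
    barrier clearances are fixed at their ``base_drug`` values unless
    estimated.  Optimization runs in log-space with Nelder-Mead from
    ``config.n_starts`` jittered starting points; the best objective wins,
    ties broken by first convergence.
    """
    if len(patients) < 2:
        raise ValueError("population fit requires at least 2 subjects")
    engine = PredictionEngine(
        patients, sys, base_drug, apply_recovery=config.apply_recovery
    )
    names = list(PARAM_NAMES) + (list(PS_NAMES) if config.estimate_ps else [])
    start = _default_start(patients)
    start["PS_ECF"] = base_drug.PS_ECF
    start["PS_CSF"] = base_drug.PS_CSF
    start.update(config.start)
    free = [n for n in names if n not in config.fix]
    x0 = np.log([start[n] for n in free])

    state = {"eta": np.zeros(engine.n_sub), "trace": [], "best": np.inf}

    def objective(x: np.ndarray) -> float:
        vals = dict(zip(free, np.exp(x)))
        vals.update(config.fix)
        m2ll, eta = engine.laplace_m2ll(
            vals["CL"],
            vals["Kp"],
            vals["omega_cl"],
            {k: vals[k] for k in PARAM_NAMES[3:]},
            ps_ecf=vals.get("PS_ECF"),
            ps_csf=vals.get("PS_CSF"),
            eta0=state["eta"],
            inner_iters=config.inner_iters,
        )
        if np.isfinite(m2ll):
            state["eta"] = eta
        if m2ll < state["best"]:
            state["best"] = m2ll
            state["trace"].append(m2ll)
        return m2ll if np.isfinite(m2ll) else 1e12

    rng = np.random.default_rng(config.seed)
    best = None
    for k in range(max(config.n_starts, 1)):
        xk = x0 if k == 0 else x0 + rng.normal(0.0, 0.15, size=x0.size)
        res = minimize(
            objective,
            xk,
            method="Nelder-Mead",
            options={
                "maxiter": config.maxiter,
                "xatol": config.xatol,
                "fatol": config.fatol,
            },
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    # refresh subject modes at the optimum
    objective(best.x)
    vals = dict(zip(free, np.exp(best.x)))
    vals.update(config.fix)

    theta_names = ["CL", "Kp"] + (list(PS_NAMES) if config.estimate_ps else [])
    fixed = {"fd": base_drug.fd}
    if not config.estimate_ps:
        fixed["PS_ECF"] = base_drug.PS_ECF
        fixed["PS_CSF"] = base_drug.PS_CSF
    fixed.update(config.fix)
    return PopulationFit(
        theta={n: float(vals[n]) for n in theta_names if n not in config.fix},
        fixed=fixed,
        omega_cl=float(vals["omega_cl"]),
        sigmas={k: float(vals[k]) for k in PARAM_NAMES[3:]},
        objective=float(best.fun),
        converged=bool(best.success),
        n_subjects=len(patients),
        etas={p.subject_id: float(e) for p, e in zip(patients, state["eta"])},
        trace=state["trace"],
    )


def bootstrap_ci(
    patients: list[PatientRecord],
    fit: PopulationFit,
    sys: SystemParameters = SystemParameters(),
    base_drug: DrugParameters = DrugParameters(),
    config: FitConfig = FitConfig(),
    n_boot: int = 200,
    seed: int = 0,
    max_failure_fraction: float = 0.2,
) -> dict:
    """Percentile bootstrap confidence intervals by subject resampling.

    Cohorts of the original size are drawn with replacement, refitted from
    the original estimates, and 2.5/97.5 percentiles of each parameter are
    reported.  Raises if more than ``max_failure_fraction`` of refits fail.
    """
    if len(patients) < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    refit_cfg = dataclasses.replace(
        config,
        n_starts=1,
        start={**fit.theta, "omega_cl": fit.omega_cl, **fit.sigmas},
    )
    samples: dict[str, list[float]] = {}
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(patients), size=len(patients))
        boot = [
            dataclasses.replace(patients[i], subject_id=f"{patients[i].subject_id}#{k}")
            for k, i in enumerate(idx)
        ]
        try:
            bfit = fit_population(boot, sys, base_drug, refit_cfg)
        except Exception:
            failures += 1
            continue
        if not np.isfinite(bfit.objective):
            failures += 1
            continue
        for name, value in {
            **bfit.theta,
            "omega_cl": bfit.omega_cl,
            **bfit.sigmas,
        }.items():
            samples.setdefault(name, []).append(value)
    if failures > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"bootstrap unreliable: {failures}/{n_boot} refits failed"
        )
    return {
        name: (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
        for name, vals in samples.items()
    }


def fold_error(pred_auc, obs_auc) -> float:
    """Geometric-mean fold error of predicted over observed AUCs."""
    pred = np.asarray(pred_auc, float)
    obs = np.asarray(obs_auc, float)
    if np.any(pred <= 0) or np.any(obs <= 0):
        raise ValueError("AUCs must be strictly positive")
    return float(np.exp(np.mean(np.log(pred / obs))))
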