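"""Model-evaluation diagnostics: visual predictive check and GOF summaries."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import PatientRecord, STREAMS
from .estimate import PopulationFit, PredictionEngine, fold_error
from .parameters import DrugParameters, SystemParameters
from .simulate import auc_trapezoid


def _simulate_replicates(
    engine: PredictionEngine,
    fit: PopulationFit,
    n_sim: int,
    rng: np.random.Generator,
    chunk: int = 64,
) -> np.ndarray:
    """Replicate observation matrices (n_sim, n_obs) under the fitted model."""
    drug = fit.drug(engine.base_drug)
    sig = fit.sigmas
    sp = np.array(
        [sig["sigma_prop_plasma"], sig["sigma_prop_ecf"], sig["sigma_prop_csf"]]
    )[engine.stream_code]
    sa = np.where(engine.stream_code == 0, sig["sigma_add_plasma"], 0.0)
    out = np.empty((n_sim, engine.n_obs))
    done = 0
    while done < n_sim:
        p = min(chunk, n_sim - done)
        etas = rng.normal(0.0, fit.omega_cl, size=(p, engine.n_sub))
        preds = engine.predict(
            drug.CL * np.exp(etas),
            drug.Kp,
            fit.theta.get("PS_ECF", fit.fixed.get("PS_ECF")),
            fit.theta.get("PS_CSF", fit.fixed.get("PS_CSF")),
        )
        noise = preds * (1.0 + sp * rng.normal(size=preds.shape)) + sa * rng.normal(
            size=preds.shape
        )
        out[done : done + p] = noise
        done += p
    return out


def vpc(
    patients: list[PatientRecord],
    fit: PopulationFit,
    sys: SystemParameters = SystemParameters(),
    base_drug: DrugParameters = DrugParameters(),
    n_sim: int = 1000,
    seed: int = 0,
    apply_recovery: bool = False,
) -> pd.DataFrame:
    """Visual predictive check at the design of the dataset.

    ``n_sim`` replicate cohorts are simulated under the fitted model with
    the observed subjects' own sampling schedules, drain flows and
    covariates.  For every observation slot the 5th/50th/95th percentiles
    of the replicate values form the prediction band.  Returns one row per
    observation: subject, stream, (mid-)time, observed value, band and an
    ``within`` flag.  A stream with no observations is omitted with a
    warning.
    """
    engine = PredictionEngine(patients, sys, base_drug, apply_recovery=apply_recovery)
    present = {s for p in patients for s in (o.stream for o in p.observations)}
    for s in STREAMS:
        if s not in present:
            warnings.warn(f"no observations in stream {s!r}; panel omitted")
    rng = np.random.default_rng(seed)
    sims = _simulate_replicates(engine, fit, n_sim, rng)
    p5, p50, p95 = np.percentile(sims, [5.0, 50.0, 95.0], axis=0)

    rows = []
    k = 0
    for p in patients:
        for o in p.observations:
            rows.append(
                {
                    "subject": p.subject_id,
                    "stream": o.stream,
                    "time": o.midpoint,
                    "dv": o.value,
                    "p5": p5[k],
                    "p50": p50[k],
                    "p95": p95[k],
                    "within": bool(p5[k] <= o.value <= p95[k]),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def _observed_auc(p: PatientRecord, stream: str) -> tuple[np.ndarray, np.ndarray]:
    obs = p.stream(stream)
    times = np.array([o.midpoint for o in obs])
    values = np.array([o.value for o in obs])
    order = np.argsort(times)
    return times[order], values[order]


def gof_table(
    patients: list[PatientRecord],
    fit: PopulationFit,
    sys: SystemParameters = SystemParameters(),
    base_drug: DrugParameters = DrugParameters(),
    apply_recovery: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Goodness-of-fit summaries from individual (post-hoc) predictions.

    Returns ``(obs_pred, auc, mfe)``: observed-vs-predicted pairs with
    residuals; per-subject per-stream AUC over the dosing interval by the
    linear trapezoidal rule with the predicted-over-observed fold error;
    and the geometric-mean fold error per stream.
    """
    engine = PredictionEngine(patients, sys, base_drug, apply_recovery=apply_recovery)
    drug = fit.drug(base_drug)
    etas = fit.etas
    if not all(p.subject_id in etas for p in patients):
        # post-hoc (empirical Bayes) modes at the fitted parameters
        _, modes = engine.laplace_m2ll(
            drug.CL,
            drug.Kp,
            fit.omega_cl,
            fit.sigmas,
            ps_ecf=drug.PS_ECF,
            ps_csf=drug.PS_CSF,
        )
        etas = {p.subject_id: float(e) for p, e in zip(patients, modes)}
    cl_i = np.array([drug.CL * np.exp(etas[p.subject_id]) for p in patients])
    preds = engine.predict(
        cl_i[None, :],
        drug.Kp,
        fit.theta.get("PS_ECF", fit.fixed.get("PS_ECF")),
        fit.theta.get("PS_CSF", fit.fixed.get("PS_CSF")),
    )[0]

    rows = []
    k = 0
    for p in patients:
        for o in p.observations:
            rows.append(
                {
                    "subject": p.subject_id,
                    "stream": o.stream,
                    "time": o.midpoint,
                    "dv": o.value,
                    "ipred": preds[k],
                    "residual": o.value - preds[k],
                }
            )
            k += 1
    obs_pred = pd.DataFrame(rows)

    auc_rows = []
    for p in patients:
        sub = obs_pred[obs_pred.subject == p.subject_id]
        for stream in STREAMS:
            ss = sub[sub.stream == stream].sort_values("time")
            if len(ss) < 2:
                continue
            auc_obs = auc_trapezoid(ss.time.values, ss.dv.values)
            auc_pred = auc_trapezoid(ss.time.values, ss.ipred.values)
            auc_rows.append(
                {
                    "subject": p.subject_id,
                    "stream": stream,
                    "auc_obs": auc_obs,
                    "auc_pred": auc_pred,
                    "fold_error": auc_pred / auc_obs,
                }
            )
    auc = pd.DataFrame(auc_rows)
    mfe = {
        stream: fold_error(grp.auc_pred.values, grp.auc_obs.values)
        for stream, grp in auc.groupby("stream")
    }
    return obs_pred, auc, mfe
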