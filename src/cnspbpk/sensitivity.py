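"""One-at-a-time sensitivity analyses for pathophysiological change and EVD.

Brain injury can increase barrier permeability (tight-junction disruption,
2-5x), increase brain ECF volume (oedema, up to +40%) and reduce cerebral
blood flow (oligemia to critical ischemia, down to 20% of normal).  Each
scenario varies exactly one of these while all other parameters stay at
their reference values, simulates a single 500 mg 30-min infusion, and
reports the deviation of the ECF and CSF exposure (AUC over 0-24 h) from
baseline.  The drain sweep varies the EVD flow over its clinically
observed range, with the sink-flow coupling applied.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .model import effective_sink_flow
from .parameters import (
    DosingRegimen,
    DrugParameters,
    SystemParameters,
    derive_patient_physiology,
    scaled_ps,
)
from .simulate import evd_dose_fraction, simulate

PS_FACTORS = (1.0, 2.0, 3.0, 4.0, 5.0)
V_ECF_FACTORS = (1.0, 1.1, 1.2, 1.3, 1.4)
Q_BRAIN_FACTORS = (0.2, 0.4, 0.7, 1.0)
Q_EVD_GRID = (0.0, 0.001, 0.005, 0.01, 0.02, 0.03, 0.04)

_DEFAULT_TBW = 90.0  # reference body weight, kg


def scenario_parameters(
    parameter: str,
    factor: float,
    sys: SystemParameters,
    drug: DrugParameters,
) -> tuple[SystemParameters, DrugParameters]:
    """Parameter sets for one scenario: exactly one quantity rescaled.

    ``parameter`` is one of ``PS_ECF/CSF`` (both barrier clearances,
    keeping their 2:1 ratio), ``V_ECF`` or ``Q_brain``.
    """
    if factor <= 0:
        raise ValueError("scenario factor must be strictly positive")
    if parameter == "PS_ECF/CSF":
        return sys, scaled_ps(drug, factor)
    if parameter == "V_ECF":
        return dataclasses.replace(sys, V_ECF=sys.V_ECF * factor), drug
    if parameter == "Q_brain":
        return dataclasses.replace(sys, Q_brain=sys.Q_brain * factor), drug
    raise ValueError(f"unknown sweep parameter {parameter!r}")


def _single_dose_aucs(
    sys: SystemParameters,
    drug: DrugParameters,
    tbw: float,
    regimen: DosingRegimen,
    t_end: float,
    q_evd: float = 0.0,
) -> tuple[float, float]:
    phys = derive_patient_physiology(tbw, sys, drug.fd)
    res = simulate(
        sys, drug, phys, regimen, q_evd if q_evd > 0 else None,
        n_doses=1, t_end=t_end, grid_step=0.25,
    )
    return res.auc("ecf", 0.0, t_end), res.auc("csf", 0.0, t_end)


def sweep_pathophysiology(
    sys: SystemParameters = SystemParameters(),
    drug: DrugParameters = DrugParameters(),
    tbw: float = _DEFAULT_TBW,
    ps_factors=PS_FACTORS,
    v_ecf_factors=V_ECF_FACTORS,
    q_brain_factors=Q_BRAIN_FACTORS,
    regimen: DosingRegimen = DosingRegimen(),
    t_end: float = 24.0,
) -> pd.DataFrame:
    """Single-dose AUC deviations under pathophysiological parameter changes.

    Returns one row per scenario: varied parameter, factor, ECF and CSF
    AUC over 0-``t_end`` h and their percent deviation from baseline.
    """
    base_ecf, base_csf = _single_dose_aucs(sys, drug, tbw, regimen, t_end)
    rows = [
        {
            "parameter": "baseline",
            "factor": 1.0,
            "auc_ecf": base_ecf,
            "auc_csf": base_csf,
            "dev_ecf_pct": 0.0,
            "dev_csf_pct": 0.0,
        }
    ]
    sweeps = (
        ("PS_ECF/CSF", ps_factors),
        ("V_ECF", v_ecf_factors),
        ("Q_brain", q_brain_factors),
    )
    for parameter, factors in sweeps:
        for f in factors:
            s2, d2 = scenario_parameters(parameter, f, sys, drug)
            auc_ecf, auc_csf = _single_dose_aucs(s2, d2, tbw, regimen, t_end)
            rows.append(
                {
                    "parameter": parameter,
                    "factor": f,
                    "auc_ecf": auc_ecf,
                    "auc_csf": auc_csf,
                    "dev_ecf_pct": 100.0 * (auc_ecf - base_ecf) / base_ecf,
                    "dev_csf_pct": 100.0 * (auc_csf - base_csf) / base_csf,
                }
            )
    return pd.DataFrame(rows)


def sweep_evd(
    sys: SystemParameters = SystemParameters(),
    drug: DrugParameters = DrugParameters(),
    tbw: float = _DEFAULT_TBW,
    q_grid=Q_EVD_GRID,
    regimen: DosingRegimen = DosingRegimen(),
    t_end: float = 24.0,
) -> pd.DataFrame:
    """Effect of the EVD flow on CSF exposure and dose recovery.

    For each drain flow (including the no-drain case) the sink-flow
    coupling is applied, a single dose gives the CSF AUC over 0-``t_end``
    h, and a steady-state simulation gives the percent of the dose
    recovered in the collection bag over one dosing interval.
    """
    rows = []
    base_auc = None
    for q in q_grid:
        if q < 0:
            raise ValueError("Q_EVD must be non-negative")
        _, auc_csf = _single_dose_aucs(sys, drug, tbw, regimen, t_end, q_evd=q)
        phys = derive_patient_physiology(tbw, sys, drug.fd)
        ss = simulate(sys, drug, phys, regimen, q if q > 0 else None, grid_step=0.25)
        frac = evd_dose_fraction(ss, q) if q > 0 else 0.0
        if base_auc is None and q == 0:
            base_auc = auc_csf
        rows.append(
            {
                "q_evd": q,
                "q_sink": effective_sink_flow(q, sys.Q_sink_physio),
                "auc_csf": auc_csf,
                "dose_fraction_pct": frac,
            }
        )
    df = pd.DataFrame(rows)
    ref = base_auc if base_auc is not None else df.auc_csf.iloc[0]
    df["dev_csf_pct"] = 100.0 * (df.auc_csf - ref) / ref
    return df
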