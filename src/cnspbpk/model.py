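"""Assembly of the linear compartmental system.

The state vector is stored as *amounts* (mg) in six compartments::

    0  blood
    1  lumped non-CNS tissue
    2  brain vasculature
    3  brain extracellular fluid (ECF)
    4  cranial cerebrospinal fluid (CSF)
    5  EVD collection bag (absorbing, cumulative amount)

Concentrations follow by dividing by the compartment volume.  All exchange
is passive and linear, so the dynamics are ``dA/dt = M A + Input * e_blood``
with a constant rate matrix ``M`` (1/h) per piecewise-constant segment.

Drug moves between blood and tissue by perfusion (``fd * CO``, with the
return flow scaled by 1/Kp), between blood and brain vasculature by cerebral
blood flow, across the BBB and BCSFB by the bidirectional permeability-
surface clearances ``PS_ECF`` and ``PS_CSF``, from ECF to CSF by bulk flow,
and from CSF back to the vasculature by the reabsorption (sink) flow.  An
external ventricular drain removes CSF at ``Q_EVD`` into the absorbing bag
and reduces the physiological sink flow by the same amount (clamped at
zero).  Elimination is a total blood clearance ``CL`` acting on the blood
compartment.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    DrugParameters,
    PatientPhysiology,
    SystemParameters,
)

N_STATES = 6
STATES = ("blood", "tissue", "brain_vasc", "ecf", "csf", "evd")

#: column index of each compartment in the state vector
BLOOD, TISSUE, BRAIN_VASC, ECF, CSF, EVD = range(N_STATES)


def effective_sink_flow(q_evd: float, q_sink_physio: float) -> float:
    """CSF reabsorption flow remaining once the drain takes ``q_evd``.

    The drain is assumed to substitute for blocked physiological CSF
    outflow, so the sink flow is reduced by the drain flow and floored at
    zero when the drain exceeds the physiological value.
    """
    if q_evd < 0 or q_sink_physio < 0:
        raise ValueError("flows must be non-negative")
    return max(q_sink_physio - q_evd, 0.0)


def compartment_volumes(
    sys: SystemParameters, phys: PatientPhysiology
) -> np.ndarray:
    """Volumes (L) used to convert amounts to concentrations.

    The EVD bag is tracked as an amount; its slot holds 1.0 so division is
    a no-op (the per-interval bag volume converts it to a concentration).
    """
    return np.array(
        [sys.V_blood, phys.V_tissue, sys.V_brain_vasc, sys.V_ECF, sys.V_CSF, 1.0]
    )


def build_transfer_matrix(
    sys: SystemParameters,
    drug: DrugParameters,
    phys: PatientPhysiology,
    q_evd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Amount-space rate matrix and unit input vector.

    Returns ``(M, u)`` with ``M`` the 6x6 rate matrix (1/h) and ``u`` the
    unit input mapping (infusion enters the blood compartment), such that
    ``dA/dt = M A + rate * u``.

    Off-diagonal entries are non-negative; every column of ``M`` sums to
    ``-CL/V_blood`` for blood and zero elsewhere, so mass is conserved up
    to blood clearance (the EVD bag being part of the state).
    """
    q_sink = effective_sink_flow(q_evd, sys.Q_sink_physio)
    vols = compartment_volumes(sys, phys)

    # F[i, j]: clearance (L/h) acting on C_j moving drug from j into i
    F = np.zeros((N_STATES, N_STATES))
    F[TISSUE, BLOOD] = drug.fd * sys.CO
    F[BLOOD, TISSUE] = drug.fd * sys.CO / drug.Kp
    F[BRAIN_VASC, BLOOD] = sys.Q_brain
    F[BLOOD, BRAIN_VASC] = sys.Q_brain
    F[ECF, BRAIN_VASC] = drug.PS_ECF
    F[BRAIN_VASC, ECF] = drug.PS_ECF
    F[CSF, BRAIN_VASC] = drug.PS_CSF
    F[BRAIN_VASC, CSF] = drug.PS_CSF + q_sink
    F[CSF, ECF] = sys.Q_bulk
    F[EVD, CSF] = q_evd

    out = F.sum(axis=0)
    out[BLOOD] += drug.CL  # irreversible elimination from blood

    M = F / vols[np.newaxis, :]
    M[np.diag_indices(N_STATES)] -= out / vols

    u = np.zeros(N_STATES)
    u[BLOOD] = 1.0
    return M, u
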