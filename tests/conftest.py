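import numpy as np
import pytest

from cnspbpk import (
    CohortDesign,
    DosingRegimen,
    DrugParameters,
    PopulationTruth,
    SystemParameters,
    derive_patient_physiology,
)


@pytest.fixture(scope="session")
def sys_params():
    return SystemParameters()


@pytest.fixture(scope="session")
def drug():
    return DrugParameters()


@pytest.fixture(scope="session")
def phys(sys_params, drug):
    return derive_patient_physiology(90.0, sys_params, drug.fd)


@pytest.fixture(scope="session")
def regimen():
    return DosingRegimen()


@pytest.fixture(scope="session")
def truth():
    return PopulationTruth()


@pytest.fixture(scope="session")
def design():
    return CohortDesign()


def rhs_concentrations(sys, drug, phys, q_evd, c, input_rate):
    """Direct transcription of the model equations in concentration form.

    Independent oracle for the matrix assembly: returns the time
    derivatives of (C_B, C_tissue, C_brain_vasc, C_ECF, C_CSF) and of the
    EVD-bag amount.
    """
    q_sink = max(sys.Q_sink_physio - q_evd, 0.0)
    c_b, c_t, c_v, c_e, c_c = c
    d_b = (
        input_rate
        + drug.fd * sys.CO * c_t / drug.Kp
        + sys.Q_brain * c_v
        - c_b * (drug.fd * sys.CO + sys.Q_brain + drug.CL)
    ) / sys.V_blood
    d_t = drug.fd * sys.CO * (c_b - c_t / drug.Kp) / phys.V_tissue
    d_v = (
        sys.Q_brain * c_b
        + drug.PS_ECF * c_e
        + c_c * (drug.PS_CSF + q_sink)
        - c_v * (sys.Q_brain + drug.PS_ECF + drug.PS_CSF)
    ) / sys.V_brain_vasc
    d_e = (c_v * drug.PS_ECF - c_e * (drug.PS_ECF + sys.Q_bulk)) / sys.V_ECF
    d_c = (
        c_v * drug.PS_CSF
        + c_e * sys.Q_bulk
        - c_c * (drug.PS_CSF + q_sink + q_evd)
    ) / sys.V_CSF
    d_evd = c_c * q_evd
    return np.array([d_b, d_t, d_v, d_e, d_c, d_evd])
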