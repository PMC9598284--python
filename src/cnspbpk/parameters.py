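"""Parameter containers for the minimal CNS PBPK model.

The model describes drug disposition with five physiological compartments
(blood, lumped non-CNS tissue, brain vasculature, brain extracellular fluid
and cranial cerebrospinal fluid) plus an absorbing external-ventricular-drain
(EVD) collection bag.  All quantities use a fixed unit system: hours, litres,
milligrams and mg/L; surface area in cm^2 per gram of brain and brain mass in
grams.  No unit conversion happens inside the core model.

``SystemParameters`` holds the physiological constants (flows and volumes),
``DrugParameters`` the drug-specific quantities, and
:func:`derive_patient_physiology` closes the volume balance for an individual
patient of known body weight.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence


class ValidationError(ValueError):
    """Raised when a parameter set violates a physiological constraint."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


@dataclass(frozen=True)
class SystemParameters:
    """Physiological (drug-independent) model constants.

    Defaults are literature values for an adult:

    ==============  =======================================  ==========
    field           meaning                                  default
    ==============  =======================================  ==========
    Q_bulk          ECF -> CSF bulk flow (L/h)               0.0105
    Q_sink_physio   physiological CSF reabsorption (L/h)     0.024
    CO              cardiac output (L/h)                     312
    Q_brain         cerebral blood flow (L/h)                42
    V_ECF           brain extracellular fluid volume (L)     0.24
    V_CSF           cranial CSF volume (L)                   0.130
    V_blood         blood volume (L)                         5.85
    V_brain_vasc    brain vascular volume (L)                0.0637
    SA_BBB          BBB surface area (cm^2 per g brain)      157
    B_W             brain weight (g)                         1274
    ==============  =======================================  ==========
    """

    Q_bulk: float = 0.0105
    Q_sink_physio: float = 0.024
    CO: float = 312.0
    Q_brain: float = 42.0
    V_ECF: float = 0.24
    V_CSF: float = 0.130
    V_blood: float = 5.85
    V_brain_vasc: float = 0.0637
    SA_BBB: float = 157.0
    B_W: float = 1274.0

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            _require(getattr(self, name.name) > 0, f"{name.name} must be strictly positive")
        _require(self.Q_brain < self.CO, "Q_brain must be smaller than cardiac output CO")


@dataclass(frozen=True)
class DrugParameters:
    """Drug-specific parameters.

    Defaults correspond to metronidazole: total blood clearance of unbound
    drug ``CL``, unbound tissue-to-blood partition coefficient ``Kp``,
    bidirectional passive permeability-surface clearances across the
    blood-brain barrier (``PS_ECF``) and blood-CSF barrier (``PS_CSF``), the
    fraction of cardiac output perfusing the lumped tissue compartment
    ``fd``, plasma unbound fraction ``fu``, blood-to-plasma concentration
    ratio ``BP_ratio`` and physicochemical metadata (``MW`` g/mol, ``logP``).
    """

    CL: float = 7.28
    Kp: float = 0.796
    PS_ECF: float = 6.4
    PS_CSF: float = 3.2
    fd: float = 0.86
    fu: float = 1.0
    BP_ratio: float = 0.82
    MW: float = 171.0
    logP: float = -0.459

    def __post_init__(self) -> None:
        _require(self.CL >= 0, "CL must be non-negative")
        _require(self.PS_ECF >= 0, "PS_ECF must be non-negative")
        _require(self.PS_CSF >= 0, "PS_CSF must be non-negative")
        _require(self.Kp > 0, "Kp must be strictly positive")
        _require(0 < self.fd < 1, "fd must be a fraction in (0, 1)")
        _require(0 < self.fu <= 1, "fu must be a fraction in (0, 1]")
        _require(self.BP_ratio > 0, "BP_ratio must be strictly positive")


def scaled_ps(drug: DrugParameters, factor: float) -> DrugParameters:
    """Return ``drug`` with both barrier clearances multiplied by ``factor``.

    The BBB and BCSFB clearances are varied together, preserving the
    half-surface-area ratio between them.
    """
    if factor <= 0:
        raise ValidationError("PS scale factor must be strictly positive")
    return dataclasses.replace(
        drug, PS_ECF=drug.PS_ECF * factor, PS_CSF=drug.PS_CSF * factor
    )


@dataclass(frozen=True)
class PatientPhysiology:
    """Individual volume balance: lumped tissue volume and brain flow fraction.

    ``V_tissue`` follows from total body weight (1 kg of body mass taken as
    1 L) minus blood, brain-vascular, ECF and CSF volumes; ``fd_brain`` is
    the fraction of cardiac output perfusing the brain, Q_brain / CO.
    """

    TBW: float
    V_tissue: float
    fd_brain: float

    def __post_init__(self) -> None:
        _require(self.TBW > 0, "TBW must be strictly positive")
        _require(self.V_tissue > 0, "V_tissue must be strictly positive")
        _require(0 < self.fd_brain < 1, "fd_brain must be a fraction in (0, 1)")


def derive_patient_physiology(
    TBW: float, sys: SystemParameters, fd: float
) -> PatientPhysiology:
    """Close the whole-body volume balance for a patient of weight ``TBW`` kg.

    The compartment volumes must sum to total body weight (taking body
    density as 1 kg/L), which fixes the lumped tissue volume::

        V_tissue = TBW - V_blood - V_brain_vasc - V_ECF - V_CSF

    and the blood-flow budget requires ``fd + Q_brain/CO <= 1``.

    Raises
    ------
    ValidationError
        If the volume balance leaves no room for the tissue compartment or
        the flow-fraction constraint is violated.
    """
    v_tissue = TBW - sys.V_blood - sys.V_brain_vasc - sys.V_ECF - sys.V_CSF
    if v_tissue <= 0:
        raise ValidationError(
            "volume balance violated: V_tissue = TBW - V_blood - V_brain_vasc "
            f"- V_ECF - V_CSF = {v_tissue:.4g} L must be positive"
        )
    fd_brain = sys.Q_brain / sys.CO
    if fd + fd_brain > 1.0:
        raise ValidationError(
            f"flow-fraction constraint violated: fd + fd_brain = {fd + fd_brain:.4g} > 1"
        )
    return PatientPhysiology(TBW=TBW, V_tissue=v_tissue, fd_brain=fd_brain)


@dataclass(frozen=True)
class DosingRegimen:
    """Intermittent intravenous infusion schedule.

    ``dose`` mg infused over ``infusion_duration`` h, repeated every ``tau``
    h.  The default is the 500 mg q8h 30-min infusion regimen.
    """

    dose: float = 500.0
    infusion_duration: float = 0.5
    tau: float = 8.0

    def __post_init__(self) -> None:
        _require(self.dose >= 0, "dose must be non-negative")
        _require(
            0 < self.infusion_duration <= self.tau,
            "infusion_duration must lie in (0, tau]",
        )

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h (1000 mg/h for the default regimen)."""
        return self.dose / self.infusion_duration


@dataclass(frozen=True)
class EVDInterval:
    """One EVD collection interval: bounds (h), drain flow (L/h), bag volume (L)."""

    t_start: float
    t_end: float
    Q_EVD: float
    V_EVD: float


@dataclass(frozen=True)
class EVDSchedule:
    """Ordered, non-overlapping EVD collection intervals.

    The drain flow is treated as piecewise constant: within interval ``k``
    the flow is ``intervals[k].Q_EVD`` and outside any interval it is zero.
    The recorded bag volume should be consistent with flow x duration; a
    mismatch beyond ``volume_rtol`` only triggers a warning because the bag
    volume may have been measured independently of the flow estimate.
    """

    intervals: tuple[EVDInterval, ...]
    volume_rtol: float = 0.05

    def __init__(
        self,
        intervals: Sequence[EVDInterval | tuple[float, float, float, float]],
        volume_rtol: float = 0.05,
    ) -> None:
        parsed = tuple(
            iv if isinstance(iv, EVDInterval) else EVDInterval(*iv) for iv in intervals
        )
        object.__setattr__(self, "intervals", parsed)
        object.__setattr__(self, "volume_rtol", volume_rtol)
        self.__post_init__()

    def __post_init__(self) -> None:
        prev_end = -float("inf")
        for iv in self.intervals:
            _require(iv.t_end > iv.t_start, "EVD interval must have t_end > t_start")
            _require(iv.t_start >= prev_end, "EVD intervals must be ordered and non-overlapping")
            _require(iv.Q_EVD >= 0, "Q_EVD must be non-negative")
            _require(iv.V_EVD > 0, "V_EVD must be strictly positive")
            expected = iv.Q_EVD * (iv.t_end - iv.t_start)
            if expected > 0 and abs(iv.V_EVD - expected) > self.volume_rtol * expected:
                warnings.warn(
                    f"EVD interval [{iv.t_start}, {iv.t_end}]: recorded volume "
                    f"{iv.V_EVD:.4g} L differs from Q_EVD*dt = {expected:.4g} L",
                    stacklevel=2,
                )
            prev_end = iv.t_end

    def flow_at(self, t: float) -> float:
        """Drain flow at time ``t`` (0 outside every collection interval)."""
        for iv in self.intervals:
            if iv.t_start <= t < iv.t_end:
                return iv.Q_EVD
        return 0.0

    def boundaries(self) -> list[float]:
        out: list[float] = []
        for iv in self.intervals:
            out.extend((iv.t_start, iv.t_end))
        return sorted(set(out))


_SYSTEM_KEYS = [f.name for f in dataclasses.fields(SystemParameters)]
_DRUG_KEYS = [f.name for f in dataclasses.fields(DrugParameters)]


def load_config(path: str | Path) -> tuple[SystemParameters, DrugParameters]:
    """Read a flat key-value config (JSON or YAML by extension).

    Keys are the field names of :class:`SystemParameters` and
    :class:`DrugParameters`; missing keys fall back to the defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a flat mapping of parameter names to numbers")
    unknown = set(raw) - set(_SYSTEM_KEYS) - set(_DRUG_KEYS)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    sys_kwargs = {k: float(raw[k]) for k in _SYSTEM_KEYS if k in raw}
    drug_kwargs = {k: float(raw[k]) for k in _DRUG_KEYS if k in raw}
    return SystemParameters(**sys_kwargs), DrugParameters(**drug_kwargs)


def dump_config(sys: SystemParameters, drug: DrugParameters, path: str | Path) -> None:
    """Write system + drug parameters as a flat JSON mapping."""
    payload = {**dataclasses.asdict(sys), **dataclasses.asdict(drug)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
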