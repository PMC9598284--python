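"""Long-format clinical-style dataset: containers and CSV dialect.

One row per event.  Dosing rows carry ``AMT`` (mg) and ``RATE`` (mg/h);
observation rows carry ``DV`` (mg/L) with ``STREAM`` one of
``plasma_unbound`` (point sample at ``TIME``), ``dialysate``
(recovery-corrected microdialysate, interval ``T1``-``T2``) or ``evd``
(EVD-bag fraction, interval ``T1``-``T2`` with per-interval ``QEVD`` L/h and
``VEVD`` L).  ``RECOVERY`` is the in vivo probe recovery for dialysate
subjects and ``WT`` the body weight in kg.  Missing fields are left empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .parameters import DosingRegimen, EVDSchedule

STREAMS = ("plasma_unbound", "dialysate", "evd")

COLUMNS = [
    "ID",
    "TIME",
    "T1",
    "T2",
    "DV",
    "STREAM",
    "AMT",
    "RATE",
    "QEVD",
    "VEVD",
    "RECOVERY",
    "WT",
]


@dataclass(frozen=True)
class ObservationRecord:
    """A single observed concentration.

    Point streams use ``time``; interval streams use ``t1``/``t2``.
    ``recovery`` applies to dialysate only; ``q_evd``/``v_evd`` to EVD only.
    """

    stream: str
    value: float
    time: float | None = None
    t1: float | None = None
    t2: float | None = None
    recovery: float | None = None
    q_evd: float | None = None
    v_evd: float | None = None

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown observation stream {self.stream!r}")
        if not self.value > 0:
            raise ValueError("observed value must be strictly positive")
        if self.stream == "plasma_unbound":
            if self.time is None:
                raise ValueError("plasma observations need a sampling time")
        else:
            if self.t1 is None or self.t2 is None or not self.t1 < self.t2:
                raise ValueError("interval observations need t1 < t2")
        if self.recovery is not None and not 0 < self.recovery <= 1:
            raise ValueError("probe recovery must lie in (0, 1]")
        if self.stream == "evd":
            if self.q_evd is None or self.q_evd < 0:
                raise ValueError("EVD observations need Q_EVD >= 0")
            if self.v_evd is None or self.v_evd <= 0:
                raise ValueError("EVD observations need V_EVD > 0")

    @property
    def midpoint(self) -> float:
        if self.stream == "plasma_unbound":
            return float(self.time)
        return 0.5 * (self.t1 + self.t2)


@dataclass
class PatientRecord:
    """One subject: covariates, dosing regimen and observations."""

    subject_id: str
    weight: float
    regimen: DosingRegimen
    observations: list[ObservationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("body weight must be strictly positive")

    def stream(self, name: str) -> list[ObservationRecord]:
        return [o for o in self.observations if o.stream == name]

    def evd_schedule(self) -> EVDSchedule | None:
        rows = [
            (o.t1, o.t2, o.q_evd, o.v_evd)
            for o in self.observations
            if o.stream == "evd"
        ]
        if not rows:
            return None
        return EVDSchedule(sorted(rows))


def _num(value) -> float | None:
    if value is None:
        return None
    v = float(value)
    return None if math.isnan(v) else v


def patients_from_frame(
    frame: pd.DataFrame, default_tau: float = 8.0
) -> list[PatientRecord]:
    """Parse a long-format dataset into per-subject records.

    Each subject needs at least one dosing row (``AMT`` and ``RATE`` set);
    the inter-dose interval is ``default_tau`` (the sampling window of the
    study design equals one dosing interval).
    """
    patients: list[PatientRecord] = []
    for sid, grp in frame.groupby("ID", sort=False):
        wt = _num(grp["WT"].dropna().iloc[0]) if grp["WT"].notna().any() else None
        if wt is None:
            raise ValueError(f"subject {sid}: missing body weight WT")
        dose_rows = grp[grp["AMT"].notna() & (grp["AMT"] > 0)]
        if dose_rows.empty:
            raise ValueError(f"subject {sid}: no dosing row")
        amt = float(dose_rows["AMT"].iloc[0])
        rate = float(dose_rows["RATE"].iloc[0])
        regimen = DosingRegimen(dose=amt, infusion_duration=amt / rate, tau=default_tau)
        obs = []
        for _, row in grp[grp["DV"].notna()].iterrows():
            obs.append(
                ObservationRecord(
                    stream=str(row["STREAM"]),
                    value=float(row["DV"]),
                    time=_num(row.get("TIME")),
                    t1=_num(row.get("T1")),
                    t2=_num(row.get("T2")),
                    recovery=_num(row.get("RECOVERY")),
                    q_evd=_num(row.get("QEVD")),
                    v_evd=_num(row.get("VEVD")),
                )
            )
        patients.append(
            PatientRecord(subject_id=str(sid), weight=wt, regimen=regimen, observations=obs)
        )
    return patients


def patients_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        rows.append(
            {
                "ID": p.subject_id,
                "TIME": 0.0,
                "AMT": p.regimen.dose,
                "RATE": p.regimen.rate,
                "WT": p.weight,
            }
        )
        for o in p.observations:
            rows.append(
                {
                    "ID": p.subject_id,
                    "TIME": o.time,
                    "T1": o.t1,
                    "T2": o.t2,
                    "DV": o.value,
                    "STREAM": o.stream,
                    "QEVD": o.q_evd,
                    "VEVD": o.v_evd,
                    "RECOVERY": o.recovery,
                    "WT": p.weight,
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def load_dataset(path: str | Path, default_tau: float = 8.0) -> list[PatientRecord]:
    return patients_from_frame(pd.read_csv(path), default_tau=default_tau)


def save_dataset(patients: list[PatientRecord] | pd.DataFrame, path: str | Path) -> None:
    frame = patients if isinstance(patients, pd.DataFrame) else patients_to_frame(patients)
    frame.to_csv(path, index=False)
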