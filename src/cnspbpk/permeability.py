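"""In-vitro-to-in-vivo permeability scaling and PS cross-comparison.

Transwell (Caco-2) apparent permeabilities are screened with the efflux
ratio (basolateral-to-apical over apical-to-basolateral); a ratio below 2
indicates purely passive transport, in which case the mean apparent
permeability is scaled to a whole-brain BBB clearance by the barrier
surface area and brain weight.  The BCSFB clearance is taken as half the
BBB clearance (half the exchange surface area).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

EFFLUX_PASSIVE_THRESHOLD = 2.0

_S_PER_H = 3600.0
_CM3_PER_L = 1000.0


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """Bidirectional transwell apparent permeabilities (cm/s)."""

    Papp_AB: float
    Papp_BA: float

    def __post_init__(self) -> None:
        if self.Papp_AB <= 0 or self.Papp_BA <= 0:
            raise ValueError("apparent permeabilities must be strictly positive")


@dataclass(frozen=True)
class EffluxResult:
    ratio: float
    passive: bool
    mean_papp: float | None


def efflux_ratio(meas: PermeabilityMeasurement) -> EffluxResult:
    """Efflux ratio Papp(B->A)/Papp(A->B) and passive-transport flag.

    A ratio below 2 is taken as evidence of purely passive diffusion; the
    mean of the two directional permeabilities is then the single passive
    Papp.  For ratios >= 2 no mean is reported (active efflux suspected).
    """
    ratio = meas.Papp_BA / meas.Papp_AB
    passive = ratio < EFFLUX_PASSIVE_THRESHOLD
    mean = 0.5 * (meas.Papp_AB + meas.Papp_BA) if passive else None
    return EffluxResult(ratio=ratio, passive=passive, mean_papp=mean)


def scale_papp_to_ps(papp: float, sa_bbb: float, b_w: float) -> float:
    """Scale an apparent permeability to a whole-brain barrier clearance.

    Parameters
    ----------
    papp : apparent permeability, cm/s.
    sa_bbb : barrier surface area, cm^2 per g brain.
    b_w : brain weight, g.

    Returns
    -------
    PS clearance in L/h:  ``papp * 3600 * sa_bbb * b_w / 1000``
    (cm/s x s/h x cm^2 = cm^3/h, divided by 1000 cm^3/L).
    """
    if papp < 0 or sa_bbb <= 0 or b_w <= 0:
        raise ValueError("papp must be >= 0 and scaling factors strictly positive")
    return papp * _S_PER_H * sa_bbb * b_w / _CM3_PER_L


def ps_csf_from_ps_ecf(ps_ecf: float) -> float:
    """BCSFB clearance under the half-surface-area assumption: PS_ECF / 2."""
    if ps_ecf < 0:
        raise ValueError("PS_ECF must be non-negative")
    return ps_ecf / 2.0


@dataclass(frozen=True)
class PSComparison:
    """Per-barrier PS values from the three determination routes (L/h)."""

    ps_ecf_calculated: float
    ps_ecf_in_vitro: float
    ps_ecf_estimated: float
    ps_csf_calculated: float | None = None
    ps_csf_in_vitro: float | None = None
    ps_csf_estimated: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "ps_ecf_calculated",
            "ps_ecf_in_vitro",
            "ps_ecf_estimated",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # missing BCSFB entries follow the halving rule
        for ecf, csf in (
            ("ps_ecf_calculated", "ps_csf_calculated"),
            ("ps_ecf_in_vitro", "ps_csf_in_vitro"),
            ("ps_ecf_estimated", "ps_csf_estimated"),
        ):
            if getattr(self, csf) is None:
                object.__setattr__(self, csf, ps_csf_from_ps_ecf(getattr(self, ecf)))
            elif getattr(self, csf) <= 0:
                raise ValueError(f"{csf} must be strictly positive")


def fold_ratio(a: float, b: float) -> float:
    """Fold ratio a/b rounded to one decimal (reporting convention)."""
    if a <= 0 or b <= 0:
        raise ValueError("fold ratios require strictly positive values")
    return round(a / b, 1)


def ps_comparison_table(cmp: PSComparison) -> pd.DataFrame:
    """Cross-comparison of PS values with fold ratios versus the estimate.

    One row per barrier with the three PS determinations and the fold
    ratios of the calculated and in-vitro values over the model estimate,
    rounded to one decimal.
    """
    rows = []
    for barrier, calc, vitro, est in (
        ("PS_ECF", cmp.ps_ecf_calculated, cmp.ps_ecf_in_vitro, cmp.ps_ecf_estimated),
        ("PS_CSF", cmp.ps_csf_calculated, cmp.ps_csf_in_vitro, cmp.ps_csf_estimated),
    ):
        rows.append(
            {
                "barrier": barrier,
                "PS_calculated": calc,
                "PS_in_vitro": vitro,
                "PS_estimated": est,
                "calculated_over_estimated": fold_ratio(calc, est),
                "in_vitro_over_estimated": fold_ratio(vitro, est),
            }
        )
    return pd.DataFrame(rows)


def estimated_barrier_ratio(cmp: PSComparison) -> float:
    """Estimated PS_ECF : PS_CSF ratio, one decimal (2 expected if the
    half-surface-area assumption holds)."""
    return fold_ratio(cmp.ps_ecf_estimated, cmp.ps_csf_estimated)
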