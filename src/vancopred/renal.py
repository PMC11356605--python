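"""Renal function estimation by the Cockcroft-Gault equation.

Creatinine clearance (Ccr) drives the population-PK clearance model, so this
module is deliberately small and exact:

    Ccr (mL/min) = (140 - age) * weight / (72 * Scr)   [* 0.85 if female]

Serum creatinine below 0.6 mg/dL is rounded up to 0.6 before entering the
equation. Low Scr in elderly patients frequently reflects reduced muscle mass
rather than good filtration, and the TDM software this pipeline mirrors applies
the same convention. The rounding applies *only* inside the Ccr computation;
subgroup stratification elsewhere uses the raw laboratory value.

No upper cap is applied to Ccr: the clearance model used downstream scales
linearly with Ccr over its whole range (cohorts here reach ~135 mL/min).
"""

from __future__ import annotations

from dataclasses import dataclass

SCR_FLOOR_MG_DL = 0.6

_SEX_FEMALE_FACTOR = 0.85


@dataclass(frozen=True)
class RenalResult:
    """Creatinine clearance with the effective (rounded) Scr that produced it."""

    scr_effective: float  # mg/dL, >= 0.6
    ccr_ml_min: float
    ccr_l_h: float


def effective_scr(scr: float) -> float:
    """Serum creatinine after the round-up-to-0.6 rule (mg/dL).

    Values below 0.6 mg/dL are replaced by 0.6; values at or above pass
    through unchanged.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    return max(scr, SCR_FLOOR_MG_DL)


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    Parameters
    ----------
    age : years
    weight : actual body weight, kg
    scr : raw serum creatinine, mg/dL (the 0.6 floor is applied internally)
    sex : ``"male"`` or ``"female"``; the female result is 0.85x the male one.
    """
    if not 0 < age < 140:
        raise ValueError(f"age must be in (0, 140) years, got {age}")
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    scr_eff = effective_scr(scr)
    ccr = (140.0 - age) * weight / (72.0 * scr_eff)
    if sex == "female":
        ccr *= _SEX_FEMALE_FACTOR
    return ccr


def ccr_to_l_per_h(ccr_ml_min: float) -> float:
    """Convert creatinine clearance from mL/min to L/h (x 0.06)."""
    if ccr_ml_min < 0:
        raise ValueError(f"creatinine clearance must be non-negative, got {ccr_ml_min}")
    return ccr_ml_min * 0.06


def renal_result(age: float, weight: float, scr: float, sex: str) -> RenalResult:
    """Bundle effective Scr with Ccr in both unit systems."""
    ccr = cockcroft_gault(age, weight, scr, sex)
    return RenalResult(
        scr_effective=effective_scr(scr),
        ccr_ml_min=ccr,
        ccr_l_h=ccr_to_l_per_h(ccr),
    )
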