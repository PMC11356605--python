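"""Two-compartment intravenous-infusion PK engine.

The disposition model is the standard linear two-compartment system with
zero-order (constant-rate) infusion input into the central compartment:

    dA1/dt = R(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2
    C(t)   = A1 / V1        [mg/L == ug/mL]

Population parameters follow the Yasuhara vancomycin model used by Japanese
TDM software: clearance proportional to creatinine clearance,

    CL (L/h)  = 0.797 x Ccr (L/h)
    Vdss (L)  = 60.7
    K12 (1/h) = 0.525
    K21 (1/h) = 0.213

The model is published in macro form only; the central volume is recovered
through the steady-state volume identity V1 = Vdss / (1 + K12/K21), and the
hybrid rate constants alpha > beta are the roots of

    s^2 - (k10 + k12 + k21) s + k10 k21 = 0,    k10 = CL / V1.

Concentrations under a multi-infusion regimen are evaluated in closed form by
superposition of per-dose biexponential step responses; this is exact for the
stated ODE system (a Runge-Kutta integrator lives in :mod:`vancopred.ode` as a
validation oracle and is never on the analysis path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Dose, Regimen
from .renal import ccr_to_l_per_h

__all__ = [
    "PKParameters",
    "yasuhara_parameters",
    "derive_disposition",
    "concentration_at",
    "predict_trough",
    "steady_state_trough",
    "default_sample_time",
    "YASUHARA_CL_SLOPE",
    "YASUHARA_VDSS_L",
    "YASUHARA_K12",
    "YASUHARA_K21",
]

# Population values of the Yasuhara vancomycin model
YASUHARA_CL_SLOPE = 0.797   # CL (L/h) per Ccr (L/h)
YASUHARA_VDSS_L = 60.7
YASUHARA_K12 = 0.525        # central -> peripheral, 1/h
YASUHARA_K21 = 0.213        # peripheral -> central, 1/h


@dataclass(frozen=True)
class PKParameters:
    """Macro two-compartment parameters plus the derived micro-constants."""

    cl: float       # clearance, L/h
    vdss: float     # steady-state distribution volume, L
    k12: float      # 1/h
    k21: float      # 1/h
    v1: float       # central volume, L
    k10: float      # elimination rate constant, 1/h
    alpha: float    # fast hybrid rate constant, 1/h
    beta: float     # slow hybrid rate constant, 1/h

    @classmethod
    def from_macro(cls, cl: float, vdss: float, k12: float, k21: float) -> "PKParameters":
        v1, k10, alpha, beta = derive_disposition(cl, vdss, k12, k21)
        return cls(cl=cl, vdss=vdss, k12=k12, k21=k21, v1=v1, k10=k10, alpha=alpha, beta=beta)


def derive_disposition(cl: float, vdss: float, k12: float, k21: float) -> tuple[float, float, float, float]:
    """Micro-constants (V1, k10, alpha, beta) from macro parameters.

    V1 = Vdss / (1 + k12/k21); alpha >= beta are the roots of
    s^2 - (k10+k12+k21) s + k10*k21 = 0. k12 = 0 is accepted as the
    one-compartment limit (then V1 = Vdss and {alpha, beta} = {k10, k21}).
    """
    if cl <= 0 or vdss <= 0 or k21 <= 0 or k12 < 0:
        raise ValueError("cl, vdss, k21 must be positive and k12 non-negative")
    v1 = vdss / (1.0 + k12 / k21)
    k10 = cl / v1
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p
    if disc < 0:
        raise ValueError("negative discriminant: inconsistent rate constants")
    root = math.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    return v1, k10, alpha, beta


def yasuhara_parameters(
    ccr_ml_min: float,
    cl_slope: float = YASUHARA_CL_SLOPE,
    vdss: float = YASUHARA_VDSS_L,
    k12: float = YASUHARA_K12,
    k21: float = YASUHARA_K21,
) -> PKParameters:
    """Population PK parameters at a given creatinine clearance (mL/min)."""
    if ccr_ml_min <= 0:
        raise ValueError(f"creatinine clearance must be positive, got {ccr_ml_min}")
    cl = cl_slope * ccr_to_l_per_h(ccr_ml_min)
    return PKParameters.from_macro(cl=cl, vdss=vdss, k12=k12, k21=k21)


def _exp_coefficients(params: PKParameters) -> tuple[float, float]:
    """Coefficients of the biexponential unit-impulse central response.

    C_delta(t) = (1/V1) [c_a exp(-alpha t) + c_b exp(-beta t)].
    Degenerate alpha == beta cannot occur for distinct positive k10, k21.
    """
    a, b, k21 = params.alpha, params.beta, params.k21
    denom = a - b
    if denom <= 0:
        raise ValueError("alpha must exceed beta")
    return (a - k21) / denom, (k21 - b) / denom


def _step_response(params: PKParameters, t) -> np.ndarray:
    """Central concentration under a unit-rate (1 mg/h) infusion started at 0.

    Zero for t <= 0; approaches 1/CL as t -> inf.
    """
    c_a, c_b = _exp_coefficients(params)
    t = np.asarray(t, dtype=float)
    tt = np.maximum(t, 0.0)
    g = (c_a * -np.expm1(-params.alpha * tt) / params.alpha
         + c_b * -np.expm1(-params.beta * tt) / params.beta) / params.v1
    return np.where(t > 0.0, g, 0.0)


def concentration_at(params: PKParameters, regimen: Regimen, t) -> float | np.ndarray:
    """Serum (central) concentration at time(s) ``t`` (h), in ug/mL.

    Each infusion contributes ``R * (S(t - start) - S(t - start - duration))``
    where S is the unit-rate step response; the total is the superposition
    over all doses. ``t`` may be a scalar or an array.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    regimen.validate()
    conc = np.zeros_like(t_arr, dtype=float)
    for d in regimen.doses:
        rate = d.amount_mg / d.duration_h
        conc += rate * (_step_response(params, t_arr - d.start_h)
                        - _step_response(params, t_arr - d.start_h - d.duration_h))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(conc)
    return conc


def predict_trough(params: PKParameters, regimen: Regimen) -> float:
    """Concentration at the regimen's sampling time (the pre-dose trough
    when the sampling time coincides with a scheduled dose start)."""
    if regimen.sample_time_h is None:
        raise ValueError("regimen has no sample_time_h set")
    regimen.validate()
    if regimen.sample_time_h < regimen.doses[0].start_h:
        raise ValueError("sample time precedes the first dose")
    return float(concentration_at(params, regimen, regimen.sample_time_h))


def steady_state_trough(
    params: PKParameters,
    amount_mg: float,
    interval_h: float,
    duration_h: float,
    offset_h: float | None = None,
) -> float:
    """Steady-state concentration for an evenly spaced regimen, in closed form.

    ``offset_h`` is the sampling time after a dose start (default: the full
    interval, i.e. the trough immediately before the next dose). Obtained by
    geometric summation of the per-dose biexponential terms with accumulation
    factors 1 / (1 - exp(-lambda * interval)).
    """
    if amount_mg <= 0 or interval_h <= 0 or duration_h <= 0:
        raise ValueError("amount, interval and duration must be positive")
    if duration_h > interval_h:
        raise ValueError("infusion duration cannot exceed the dosing interval")
    if offset_h is None:
        offset_h = interval_h
    if not duration_h <= offset_h <= interval_h:
        raise ValueError("sampling offset must lie in [duration, interval] (post-infusion)")
    rate = amount_mg / duration_h
    c_a, c_b = _exp_coefficients(params)
    total = 0.0
    for c, lam in ((c_a, params.alpha), (c_b, params.beta)):
        single = (c / lam) * math.expm1(lam * duration_h) * math.exp(-lam * offset_h)
        total += single / -math.expm1(-lam * interval_h)
    return rate * total / params.v1


def default_sample_time(doses: list[Dose], at_or_after_h: float = 72.0) -> float:
    """TDM trough-sampling convention: immediately before the first dose
    starting at or after ``at_or_after_h`` (near-steady-state sampling); the
    last dose start if the course is shorter."""
    for d in doses:
        if d.start_h >= at_or_after_h:
            return d.start_h
    return doses[-1].start_h
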