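"""Synthetic elderly vancomycin cohorts with a mechanistic ground truth.

Real TDM datasets of this kind are rarely shareable, so every downstream
stage is exercised on simulated cohorts whose covariate structure matches a
typical Japanese geriatric vancomycin population (n = 144): median age 84.5
(range 75-99), 55.6% male, median weight 46.8 kg (26.0-78.2), median Scr
0.8 mg/dL (0.16-4.91), realized dose around 16.9 mg/kg/day, ICU prevalence
11/144, concomitant piperacillin/tazobactam 18/144.

"Measured" troughs come from a ground-truth PK model that deliberately
departs from the prediction model through configurable mechanisms:

* ``use_unrounded_scr_for_truth`` — the true clearance is driven by the raw
  serum creatinine while predictions round Scr < 0.6 up to 0.6. Rounding
  overestimates drug exposure in low-muscle-mass patients, producing
  positive bias confined to the Scr < 0.6 stratum.
* ``arc_icu_cl_multiplier`` — augmented renal clearance in ICU patients:
  their true clearance is multiplied (default 1.5), so measured troughs run
  below predictions and the ICU stratum shows the largest positive ME/MAE.
* log-normal between-patient variability on CL and Vdss, and a combined
  proportional + additive measurement-error model, floored at a small
  quantitation limit.

With every noise source and mechanism switched off the generator closes the
loop: measured == predicted for all patients and all error statistics are
exactly zero. A pure ``additive_shift`` delta on measured values is likewise
recovered exactly as ME = -delta, MAE = |delta|.

All randomness flows from a single seed through named substreams
(covariates / regimens / measurements), so cohorts are fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import Dose, Patient, Regimen
from .pk import default_sample_time, predict_trough, yasuhara_parameters
from .renal import cockcroft_gault

__all__ = [
    "GeneratorConfig",
    "sample_covariates",
    "assign_regimen",
    "simulate_measured_trough",
    "generate_cohort",
]


@dataclass
class GeneratorConfig:
    """Synthetic-cohort parameters; defaults emulate the target population."""

    n: int = 144
    seed: int = 0

    # covariates: truncated normal (age, albumin) / truncated log-normal
    # (weight, Scr), parameterized to hit the population medians with hard
    # bounds at the observed ranges
    age_mean: float = 84.5
    age_sd: float = 5.5
    age_bounds: tuple[float, float] = (75.0, 99.0)
    weight_median: float = 46.8
    weight_sigma: float = 0.20          # log-scale SD
    weight_bounds: tuple[float, float] = (26.0, 78.2)
    scr_median: float = 0.8
    scr_sigma: float = 0.35             # log-scale SD
    scr_bounds: tuple[float, float] = (0.16, 4.91)
    alb_mean: float = 2.45
    alb_sd: float = 0.6
    alb_bounds: tuple[float, float] = (1.2, 4.5)
    male_fraction: float = 0.556
    icu_prevalence: float = 11.0 / 144.0
    pipc_tazo_prevalence: float = 18.0 / 144.0

    # renal-function-guided dosing nomogram: q12h above, q24h below the Ccr
    # threshold; per-dose amount targets mg/kg rounded to vial increments
    q12h_ccr_threshold: float = 50.0
    low_ccr_threshold: float = 30.0
    dose_per_kg_mg: float = 15.0
    dose_per_kg_low_ccr_mg: float = 10.0
    dose_round_mg: float = 250.0
    infusion_duration_h: float = 1.0
    course_h: float = 96.0              # doses scheduled on [0, course_h)
    trough_at_or_after_h: float = 72.0  # pre-dose sampling near 72 h

    # ground-truth mechanisms and noise
    iiv_cl_cv: float = 0.18             # between-patient CV on true CL
    iiv_v_cv: float = 0.20              # between-patient CV on true Vdss
    residual_prop_cv: float = 0.12      # proportional measurement error
    residual_add_sd: float = 0.5        # additive measurement error, ug/mL
    additive_shift: float = 0.0         # deterministic offset on measured values
    arc_icu_cl_multiplier: float = 1.5  # augmented renal clearance in ICU
    use_unrounded_scr_for_truth: bool = True
    loq: float = 0.1                    # quantitation floor, ug/mL

    # fractions of records built to trip the exclusion screen
    short_course_frac: float = 0.0
    aki_frac: float = 0.0
    hemodialysis_frac: float = 0.0
    missing_trough_frac: float = 0.0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size must be positive, got {self.n}")
        for name in ("iiv_cl_cv", "iiv_v_cv", "residual_prop_cv", "residual_add_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("male_fraction", "icu_prevalence", "pipc_tazo_prevalence",
                     "short_course_frac", "aki_frac", "hemodialysis_frac",
                     "missing_trough_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # rejection sampling keeps the shape within the bounds
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _trunc_lognormal(rng: np.random.Generator, median, sigma, lo, hi, size) -> np.ndarray:
    out = np.exp(rng.normal(math.log(median), sigma, size))
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.exp(rng.normal(math.log(median), sigma, int(bad.sum())))
        bad = (out < lo) | (out > hi)
    return out


def sample_covariates(config: GeneratorConfig, rng: np.random.Generator | None = None) -> list[Patient]:
    """Draw demographics, labs and flags for ``config.n`` patients.

    Regimens and troughs are not yet assigned; exclusion-trigger records
    (short course, AKI Scr step, hemodialysis, missing trough) are marked
    here so the counts are exact, not binomial.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    age = _trunc_normal(rng, config.age_mean, config.age_sd, *config.age_bounds, size=n)
    weight = _trunc_lognormal(rng, config.weight_median, config.weight_sigma,
                              *config.weight_bounds, size=n)
    scr = _trunc_lognormal(rng, config.scr_median, config.scr_sigma,
                           *config.scr_bounds, size=n)
    alb = _trunc_normal(rng, config.alb_mean, config.alb_sd, *config.alb_bounds, size=n)
    male = rng.random(n) < config.male_fraction
    icu = rng.random(n) < config.icu_prevalence
    pipc = rng.random(n) < config.pipc_tazo_prevalence

    # allocate disjoint exclusion-trigger sets from a permutation so the
    # requested fractions are hit exactly
    perm = rng.permutation(n)
    counts = [int(round(f * n)) for f in (config.short_course_frac, config.aki_frac,
                                          config.hemodialysis_frac, config.missing_trough_frac)]
    if sum(counts) > n:
        raise ValueError("exclusion-trigger fractions sum to more than the cohort")
    short_idx = set(perm[: counts[0]].tolist())
    aki_idx = set(perm[counts[0]: counts[0] + counts[1]].tolist())
    hd_idx = set(perm[counts[0] + counts[1]: counts[0] + counts[1] + counts[2]].tolist())
    miss_idx = set(perm[sum(counts[:3]): sum(counts)].tolist())

    patients = []
    course_days = max(4, int(math.ceil(config.course_h / 24.0)))
    for i in range(n):
        s = float(scr[i])
        series = [(0.0, s), (48.0, s + 0.4)] if i in aki_idx else [(0.0, s), (48.0, s)]
        patients.append(Patient(
            id=f"SYN-{i:04d}",
            age=float(age[i]),
            sex="male" if male[i] else "female",
            weight_kg=float(weight[i]),
            scr_mg_dl=s,
            alb_g_dl=float(alb[i]),
            icu_admission=bool(icu[i]),
            pipc_tazo=bool(pipc[i]),
            on_hemodialysis=i in hd_idx,
            died_within_30d=False,
            course_days=3 if i in short_idx else course_days,
            scr_series=series,
            regimen=None,
            measured_trough=None if i in miss_idx else -1.0,  # placeholder, filled later
        ))
    return patients


def assign_regimen(patient: Patient, config: GeneratorConfig) -> Regimen:
    """Renal-function-guided nomogram: interval from Ccr, amount from weight.

    Ccr >= 50 mL/min -> q12h; below -> q24h. Per-dose amount targets
    15 mg/kg (10 mg/kg when Ccr < 30) rounded to 250-mg increments with a
    250-mg floor. The trough is sampled immediately before the first dose at
    or after 72 h.
    """
    ccr = cockcroft_gault(patient.age, patient.weight_kg, patient.scr_mg_dl, patient.sex)
    interval = 12.0 if ccr >= config.q12h_ccr_threshold else 24.0
    per_kg = config.dose_per_kg_mg if ccr >= config.low_ccr_threshold else config.dose_per_kg_low_ccr_mg
    amount = max(config.dose_round_mg,
                 round(per_kg * patient.weight_kg / config.dose_round_mg) * config.dose_round_mg)
    course_h = 24.0 * patient.course_days
    starts = np.arange(0.0, min(config.course_h, course_h), interval)
    doses = [Dose(float(amount), float(s), config.infusion_duration_h) for s in starts]
    regimen = Regimen(doses=doses, sample_time_h=None)
    regimen.sample_time_h = default_sample_time(doses, config.trough_at_or_after_h)
    return regimen


def realized_dose_mg_kg_day(patient: Patient) -> float:
    """Total daily dose per kg implied by the assigned regimen (first 24 h)."""
    total = sum(d.amount_mg for d in patient.regimen.doses if d.start_h < 24.0)
    return total / patient.weight_kg


def simulate_measured_trough(
    patient: Patient,
    regimen: Regimen,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Ground-truth trough with mechanistic biases, IIV and assay error.

    The true individual parameters are the population parameters evaluated
    at the patient's *true* clearance driver: Cockcroft-Gault on the
    unrounded Scr (when enabled), multiplied by the ARC factor for ICU
    patients, then perturbed log-normally. The measured value adds
    proportional and additive error and is floored at the quantitation
    limit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.use_unrounded_scr_for_truth:
        # bypass the 0.6 floor: evaluate the equation on the raw Scr
        ccr = (140.0 - patient.age) * patient.weight_kg / (72.0 * patient.scr_mg_dl)
        if patient.sex == "female":
            ccr *= 0.85
    else:
        ccr = cockcroft_gault(patient.age, patient.weight_kg, patient.scr_mg_dl, patient.sex)
    if patient.icu_admission:
        ccr *= config.arc_icu_cl_multiplier

    params = yasuhara_parameters(ccr)
    eta_cl = rng.normal(0.0, config.iiv_cl_cv) if config.iiv_cl_cv > 0 else 0.0
    eta_v = rng.normal(0.0, config.iiv_v_cv) if config.iiv_v_cv > 0 else 0.0
    if eta_cl or eta_v:
        from .pk import PKParameters
        params = PKParameters.from_macro(
            cl=params.cl * math.exp(eta_cl),
            vdss=params.vdss * math.exp(eta_v),
            k12=params.k12, k21=params.k21,
        )
    true_trough = predict_trough(params, regimen)

    eps_prop = rng.normal(0.0, config.residual_prop_cv) if config.residual_prop_cv > 0 else 0.0
    eps_add = rng.normal(0.0, config.residual_add_sd) if config.residual_add_sd > 0 else 0.0
    measured = true_trough * (1.0 + eps_prop) + eps_add + config.additive_shift
    return max(measured, config.loq)


def generate_cohort(config: GeneratorConfig) -> list[Patient]:
    """Complete synthetic cohort: covariates, regimens and measured troughs.

    Deterministic under ``config.seed``; the three stages draw from
    independent named substreams so that, e.g., changing the noise model
    does not reshuffle the covariates.
    """
    config.validate()
    rng_cov, rng_reg, rng_meas = np.random.default_rng(config.seed).spawn(3)
    patients = sample_covariates(config, rng_cov)
    del rng_reg  # the default nomogram is deterministic; stream reserved
    for p in patients:
        p.regimen = assign_regimen(p, config)
        if p.measured_trough is not None:  # placeholder => simulate
            p.measured_trough = simulate_measured_trough(p, p.regimen, config, rng_meas)
        p.validate()
    return patients
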