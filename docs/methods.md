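# Methods

`vancopred` evaluates how well a population-pharmacokinetic (PPK) model
predicts vancomycin trough concentrations in patients aged 75 years and
older, and which patient characteristics degrade that accuracy. This note
records the models, the numerical choices, and the design decisions behind
the package, in the package's own terms.

## Renal function

Creatinine clearance is estimated with the Cockcroft–Gault equation on
actual body weight,

Ccr (mL/min) = (140 − age) · weight / (72 · Scr), ×0.85 for women,

with serum creatinine below 0.6 mg/dL rounded up to 0.6 before it enters
the equation. The rounding convention compensates for the low creatinine
production of sarcopenic elderly patients, in whom a low Scr reflects low
muscle mass rather than good filtration; it is the convention built into
the TDM software whose predictions this package reproduces. Two deliberate
consequences:

* the rounding applies **only** inside the Ccr computation. Subgroup
  stratification at the 0.6 mg/dL cutoff uses the raw laboratory value —
  otherwise the low-Scr stratum would be empty by construction;
* no upper cap is applied to Ccr. The clearance model used here is linear
  in Ccr over its full range; elderly cohorts reach ~135 mL/min and are
  evaluated there as-is. (Some other vancomycin TDM software caps Ccr at
  85 mL/min; that model family is deliberately not implemented.)

The L/h form needed by the clearance model is `ccr_ml_min * 0.06`, coded
exactly that way so the published invariant `ccr_l_h == 0.06 · ccr_ml_min`
holds to the last bit.

## The prediction model

Predictions use the Yasuhara two-compartment population model standard in
Japanese vancomycin TDM:

    CL (L/h)  = 0.797 · Ccr (L/h)
    Vdss (L)  = 60.7
    K12 (1/h) = 0.525
    K21 (1/h) = 0.213

The model is published in macro form only; the central volume is recovered
from the steady-state volume identity V1 = Vdss / (1 + K12/K21) ≈ 17.5 L —
the only choice consistent with the published Vdss and transfer constants —
and k10 = CL/V1. The hybrid disposition constants α > β are the roots of
s² − (k10+k12+k21)s + k10·k21 = 0 (real and positive for any positive rate
constants).

Concentrations under a multi-infusion history solve

    dA1/dt = R(t) − (k10+k12)A1 + k21·A2
    dA2/dt = k12·A1 − k21·A2,     C = A1/V1,

with R(t) the sum of active zero-order infusion rates. The engine evaluates
the closed-form solution: each infusion contributes
R·[S(t−start) − S(t−start−duration)], where S is the biexponential
unit-rate step response

    S(t) = (1/V1) · [c_α(1−e^{−αt})/α + c_β(1−e^{−βt})/β],
    c_α = (α−k21)/(α−β),  c_β = (k21−β)/(α−β),

and the regimen response is the superposition over doses. This is exact,
so accuracy is limited only by floating point. A Runge–Kutta (DOP853)
integration of the same ODE system, with piecewise-constant R handled
segment by segment at rtol 1e−10, ships in `vancopred.ode` as an
independent validation oracle; it is never on the analysis path. The two
routes agree to ~1e−12 relative; the test suite requires 1e−6 on randomized
parameter/regimen draws.

A geometric-summation shortcut (`steady_state_trough`) gives the exact
steady-state trough for evenly spaced regimens by applying accumulation
factors 1/(1−e^{−λτ}) to each exponential term. Its equivalence with a
finite simulated history is tested at a clearance where the history is
genuinely converged: the convergence rate is e^{−βNτ}, so thirty q12h doses
reach ~2e−10 of steady state at Ccr 100 mL/min (β ≈ 0.061/h) but only
~4e−6 at Ccr 50 (β ≈ 0.035/h). The 1e−8 equivalence test therefore runs at
Ccr 100; slower clearances are covered by a monotone-accumulation test.

### Dosing conventions

The source data for analyses of this kind rarely record infusion durations
or exact sampling times, so both are conventions, not facts:

* infusion duration defaults to 1.0 h per dose (clinically standard for
  1 g vancomycin), overridable per dose;
* the trough is sampled immediately before the first dose at or after 72 h
  from the course start (the usual near-steady-state TDM timing),
  overridable per patient. Full-history superposition is the default
  prediction path; the steady-state shortcut is available explicitly.

## Error statistics

With one (prediction, measurement) pair per patient,

    ME  = Σ(C_pred − C_meas)/n      (bias)
    MAE = Σ|C_pred − C_meas|/n      (accuracy)

Both carry a 95% interval mean ± t_{n−1,0.975}·sd/√n from Student's t on
the (absolute) differences. The MAE interval construction is not uniquely
standard; the t-interval on absolute differences is used for symmetry with
ME and is the package's documented choice (the confidence level is a
parameter). Bias in a stratum is flagged *significant* when the ME interval
excludes zero; no p-values are produced, and no between-stratum tests are
performed. Strata with n = 1 report the point estimate with the CI marked
undefined; empty strata keep their row with undefined statistics.

Bland–Altman agreement reports per-patient points
((pred+meas)/2, pred−meas), the mean difference (identical to ME by
construction), the SD of differences, and limits of agreement
bias ± 1.96·SD, plus the fraction of points inside the limits.

The stratified report has 15 rows: Total, then two strata for each of sex,
body weight (50 kg), concomitant piperacillin/tazobactam, albumin
(2.5 g/dL), raw Scr (0.6 mg/dL), Ccr (30 mL/min) and ICU admission.
Numeric boundary values land in the "≥" stratum.

## Exclusion screen

Records are excluded, each with all applicable machine-readable codes, for:
administration period ≤ 3 days (4 days is included — strict reading of
"3 days or less"; course days = calendar days with at least one dose);
death during the course or within 30 days (a precomputed flag — date
arithmetic is out of scope); hemodialysis; acute kidney injury during the
course (any later Scr ≥ baseline + 0.3 mg/dL or ≥ 1.5× baseline, with
baseline = the first value of the course, the natural reading of a rise
"during the administration period"); and absent trough measurement. The
screen is a partition (each record appears exactly once on one side) and
idempotent.

## Synthetic cohort generator

No patient-level dataset of this design is publicly deposited, so the
generator produces cohorts with the covariate structure of a Japanese
geriatric vancomycin population and simulates measurements from a
mechanistic ground truth. It is first-class, tested code — the study
conditions, not a test fixture.

**Covariates.** Age ~ truncated normal(84.5, 5.5) on [75, 99]; albumin ~
truncated normal(2.45, 0.6) on [1.2, 4.5]; weight ~ truncated log-normal
(median 46.8, σ_log 0.20) on [26.0, 78.2]; Scr ~ truncated log-normal
(median 0.8, σ_log 0.35) on [0.16, 4.91]; 55.6% male; ICU prevalence
11/144; piperacillin/tazobactam 18/144. Rejection sampling enforces the
bounds without distorting the interior shape. No covariate correlation is
imposed (none is documented for such cohorts). The exact distribution
shapes are unknowable from published summaries; medians and ranges are
matched, shapes are the package's choice, and everything is overridable.

**Dosing nomogram.** Interval from the (rounded-Scr) Ccr — q12h at
≥ 50 mL/min, q24h below — and per-dose amount from weight: 15 mg/kg
(10 mg/kg when Ccr < 30) rounded to 250-mg vial increments with a 250-mg
floor. A flat 1000-mg amount was considered and rejected: it pushes the
realized median dose to ~21 mg/kg/day, outside the ~17 mg/kg/day a
population of this weight actually receives; the weight-based amounts land
the realized median at ~15–17 with range ~7–36. Doses run over a 96-h
course; the trough is sampled pre-dose at 72 h.

**Ground truth and mechanisms.** Each patient's true parameters are the
population parameters evaluated at the *true* clearance driver:

* with `use_unrounded_scr_for_truth` (default on), the true Ccr uses the
  raw Scr — so for Scr < 0.6 the true clearance exceeds the predicted one
  by the factor 0.6/Scr, yielding measured troughs below predictions and a
  positive ME confined, by construction, to the raw-Scr < 0.6 stratum;
* ICU patients' true clearance is multiplied by `arc_icu_cl_multiplier`
  (default 1.5), emulating augmented renal clearance in critical illness;
* log-normal between-patient variability multiplies true CL (CV 18%) and
  Vdss (CV 20%); the measurement adds proportional (CV 12%) and additive
  (SD 0.5 µg/mL) assay error and is floored at a 0.1 µg/mL quantitation
  limit.

The variability magnitudes are deliberately *tuned, not estimated*: they
are set so the default cohort reproduces, robustly across replicate
cohorts, the qualitative signature the mechanisms encode — the ICU stratum
carries the largest ME and MAE of all 15 report rows and the low-Scr
stratum a significantly positive ME — while keeping per-patient errors in
a plausible immunoassay/PPK range (default total MAE ≈ 2–2.5 µg/mL).
Numeric ME/MAE values of any particular real cohort are explicitly not a
target: without patient-level data only directions, orderings and
mechanism-driven signatures are reproducible, and that is all the tests
claim. Other realities the generator does not emulate: covariate
correlations, non-steady-state sampling errors, dose adjustments mid-course,
assay-specific bias, and informative missingness.

Two identities make the generator self-verifying: with all noise and
mechanisms off, measured ≡ predicted and every statistic is exactly zero
(closed loop); with only a deterministic `additive_shift` δ on measured
values, the pipeline returns ME = −δ and MAE = |δ| to machine precision.
Records designed to trip the exclusion screen (short course, an AKI Scr
step of +0.4 mg/dL at 48 h, hemodialysis, missing measurement) are
allocated as exact disjoint counts, not binomially.

**Reproducibility.** All randomness flows from one integer seed through
three named substreams (covariates / regimens / measurements) of numpy's
`default_rng`, so a cohort is bit-reproducible and changing, say, the noise
model does not reshuffle the covariates. The regimen substream is reserved
(the default nomogram is deterministic).

## Problem sizes and runtimes

Defaults keep every check cheap on a single CPU: distribution targets are
verified on one n = 5000 cohort; t-interval calibration on 1000 simulated
difference sets of n = 50; mechanism signatures on 200 replicate cohorts of
n = 144 (a few seconds total — the closed-form engine needs microseconds
per trough); ODE-oracle agreement on 20 randomized cases. The full test
suite runs in well under a minute.

## Known limitations

* V1, infusion durations and sampling times are conventions (documented
  above), not data; absolute trough predictions shift if they differ.
* The MAE confidence interval is a pragmatic t-interval on absolute
  differences; absolute differences are not normal, so its coverage is
  approximate (the ME interval is the calibrated one).
* The generator's mechanism magnitudes are design choices; passing
  signature tests shows the pipeline *detects* such mechanisms, not that a
  particular real cohort has them at these magnitudes.
* Single-trough evaluation only: no AUC computation, no Bayesian
  individual-parameter estimation, no dose-recommendation logic.
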