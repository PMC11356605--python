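# vancopred

Prediction-accuracy analysis for vancomycin therapeutic drug monitoring
(TDM) in patients aged 75 years and older.

Vancomycin dosing is individualized from serum trough concentrations, which
are predicted ahead of measurement with a population-pharmacokinetic (PPK)
model driven by renal function. In elderly patients the key input — serum
creatinine — is distorted by low muscle mass, so it is unclear how accurate
those predictions are and in which patients they fail. `vancopred`
implements the full retrospective-evaluation pipeline for this question,
for clinical pharmacists and pharmacometricians:

* **Renal function**: Cockcroft–Gault creatinine clearance
  Ccr = (140 − age)·weight/(72·Scr), ×0.85 for women, with Scr < 0.6 mg/dL
  rounded up to 0.6 (the Japanese TDM-software convention for sarcopenic
  patients), and no upper Ccr cap.
* **PK engine**: the Yasuhara two-compartment population model
  (CL = 0.797·Ccr L/h, Vdss = 60.7 L, K12 = 0.525 h⁻¹, K21 = 0.213 h⁻¹),
  with V1 = Vdss/(1 + K12/K21), evaluated in closed form under arbitrary
  multi-infusion histories by superposition of biexponential step
  responses. An independent Runge–Kutta ODE oracle validates the engine in
  the test suite.
* **Error statistics**: mean prediction error ME = Σ(C_pred − C_meas)/n
  (bias) and mean absolute error MAE = Σ|C_pred − C_meas|/n (accuracy),
  each with a Student-t 95% CI; Bland–Altman agreement with 1.96·SD limits;
  and a 15-row report stratified by sex, weight (50 kg),
  piperacillin/tazobactam, albumin (2.5 g/dL), raw Scr (0.6 mg/dL), Ccr
  (30 mL/min) and ICU admission.
* **Exclusion screen**: short courses (≤3 days), death within 30 days,
  hemodialysis, acute kidney injury (Scr rise ≥0.3 mg/dL or ≥50%), missing
  measurement — each with machine-readable reason codes.
* **Synthetic cohort generator**: seeded elderly cohorts matching the
  covariate structure of a geriatric vancomycin population (median age
  84.5, weight 46.8 kg, Scr 0.8 mg/dL), with a mechanistic ground truth —
  augmented renal clearance in ICU patients and raw-creatinine truth versus
  rounded-creatinine predictions — so the whole pipeline is testable
  without patient data.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

A single prediction from the command line — an 84-year-old, 47-kg man with
Scr 0.8 mg/dL receiving 1 g over 1 h every 24 h, trough sampled pre-dose at
72 h:

```console
$ vancopred predict --age 84 --weight 47 --scr 0.8 --sex male \
    --regimen "1000mg@0hx1h;1000mg@24hx1h;1000mg@48hx1h;1000mg@72hx1h"
Ccr: 45.69 mL/min
CL: 2.185 L/h  Vdss: 60.7 L  V1: 17.52 L  k10: 0.1247 /h
alpha: 0.8307 /h  beta: 0.0320 /h
predicted trough at 72 h: 10.25 ug/mL
```

Ccr 45.7 mL/min gives CL = 0.797 × (45.69 × 0.06) = 2.19 L/h; the
closed-form engine accumulates the four infusions and reports the 72-h
pre-dose trough, 10.25 µg/mL — inside the classical 10–15 µg/mL target
window for this regimen.

A full simulated-cohort analysis (144 patients, default mechanisms):

```console
$ vancopred analyze --simulate --seed 1 --outdir results/demo
Prediction accuracy by patient characteristics (ug/mL)
...
Total                             144 *     1.15 (  0.69,   1.61)       2.27 (  1.95,   2.60)
...
Scr (mg/dL): <0.6                  30 *     3.41 (  2.15,   4.67)       3.86 (  2.79,   4.92)
...
ICU admission: with                 9 *     4.24 (  2.35,   6.13)       4.24 (  2.35,   6.13)
ICU admission: without            135 *     0.94 (  0.48,   1.40)       2.14 (  1.82,   2.46)
...
Bland-Altman agreement (prediction - measurement)
  bias 1.15 ug/mL, SD 2.80
  95% limits of agreement: -4.34 to 6.63
  points within LOA: 93.1%
```

Reading it: predictions overshoot measurements overall (ME 1.15 µg/mL,
CI excluding 0, flagged `*`), the bias concentrates in the raw-Scr < 0.6
stratum (ME 3.41 — the rounding rule overestimates exposure exactly where
it fires) and the ICU stratum shows the largest ME and MAE (4.24 —
augmented renal clearance drains drug faster than the population model
assumes). That is the mechanistic signature the generator encodes, and the
pattern the pipeline is designed to detect in real cohorts. The `analyze`
run also writes per-patient predictions, included/excluded listings with
reason codes, the accuracy table (CSV/JSON), Bland–Altman points, and a run
manifest to the output directory.

Real data go through the same path as a delimited cohort table
(`vancopred analyze --input cohort.csv --outdir results/run`); the dosing
history travels per row as `1000mg@0hx1h;1000mg@12hx1h;…`.

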