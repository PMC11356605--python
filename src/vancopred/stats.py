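"""Prediction-error statistics and agreement analysis.

For paired predicted / measured concentrations (one pair per patient):

    ME  = sum(C_prediction - C_measured) / n      (bias)
    MAE = sum(|C_prediction - C_measured|) / n    (accuracy)

Both carry a 95% confidence interval from Student's t distribution on the
(absolute) differences; a bias is called significant when the ME interval
excludes zero — no p-values are produced. Bland-Altman agreement reports
the mean difference (bias), the SD of differences and the 95% limits of
agreement bias +/- 1.96 SD, together with the per-patient (average,
difference) points for plotting.

The stratified accuracy table mirrors a standard clinical TDM report: one
Total row plus paired rows for sex, body weight (50 kg), concomitant
piperacillin/tazobactam, albumin (2.5 g/dL), raw serum creatinine
(0.6 mg/dL), creatinine clearance (30 mL/min) and ICU admission. Numeric
cutoffs assign boundary values to the ">=" stratum; serum creatinine is
stratified on the raw laboratory value, not the rounded one used inside the
Ccr computation (otherwise the low-Scr stratum would be empty).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Patient

__all__ = [
    "AccuracySummary",
    "BlandAltmanResult",
    "StratumSpec",
    "TABLE_STRATA",
    "mean_error",
    "mean_absolute_error",
    "bland_altman",
    "stratify",
    "accuracy_table",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AccuracySummary:
    """ME or MAE with its t-based confidence interval for one stratum."""

    statistic: str          # "ME" | "MAE"
    value: float            # ug/mL
    ci_low: float           # NaN when n < 2 (CI undefined)
    ci_high: float
    n: int
    level: float = 0.95

    @property
    def ci_defined(self) -> bool:
        return not (math.isnan(self.ci_low) or math.isnan(self.ci_high))

    @property
    def excludes_zero(self) -> bool | None:
        """Whether the CI excludes 0 (significant bias); None when undefined."""
        if not self.ci_defined:
            return None
        return self.ci_low > 0.0 or self.ci_high < 0.0


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float             # mean(pred - meas), ug/mL
    sd_diff: float
    loa_lower: float        # bias - 1.96 sd
    loa_upper: float        # bias + 1.96 sd
    averages: np.ndarray    # (pred + meas) / 2 per patient
    differences: np.ndarray  # pred - meas per patient
    frac_within_loa: float


def _paired(pred, meas) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape or pred.ndim != 1:
        raise ValueError("predicted and measured must be 1-d arrays of equal length")
    if pred.size == 0:
        raise ValueError("no concentration pairs supplied")
    if np.any(np.isnan(pred)) or np.any(np.isnan(meas)):
        raise ValueError("concentration pairs must not contain missing values")
    return pred, meas


def _t_summary(statistic: str, values: np.ndarray, level: float) -> AccuracySummary:
    n = values.size
    mean = float(np.mean(values))
    if n >= 2:
        half = float(sps.t.ppf(0.5 + level / 2.0, n - 1)) * float(np.std(values, ddof=1)) / math.sqrt(n)
        lo, hi = mean - half, mean + half
    else:
        lo = hi = math.nan
    return AccuracySummary(statistic=statistic, value=mean, ci_low=lo, ci_high=hi, n=n, level=level)


def mean_error(pred, meas, level: float = 0.95) -> AccuracySummary:
    """Mean prediction error (bias), with a Student-t CI on the differences."""
    pred, meas = _paired(pred, meas)
    return _t_summary("ME", pred - meas, level)


def mean_absolute_error(pred, meas, level: float = 0.95) -> AccuracySummary:
    """Mean absolute prediction error, with a t-interval on |differences|."""
    pred, meas = _paired(pred, meas)
    return _t_summary("MAE", np.abs(pred - meas), level)


def bland_altman(pred, meas, multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bland-Altman agreement between predicted and measured concentrations."""
    pred, meas = _paired(pred, meas)
    if pred.size < 2:
        raise ValueError("Bland-Altman analysis needs at least 2 pairs")
    diff = pred - meas
    avg = (pred + meas) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    lo, hi = bias - multiplier * sd, bias + multiplier * sd
    within = float(np.mean((diff >= lo) & (diff <= hi)))
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, loa_lower=lo, loa_upper=hi,
        averages=avg, differences=diff, frac_within_loa=within,
    )


# ---------------------------------------------------------------------------
# stratification

@dataclass(frozen=True)
class StratumSpec:
    """One dichotomizing variable for the accuracy table.

    For numeric variables, the first stratum is strictly below the cutoff
    and boundary values fall in the second (">=") stratum. For boolean
    variables the first stratum is the "with" group; for sex, the male group.
    """

    variable: str                       # Patient attribute or column name
    label: str                          # row-group label
    cutoff: float | None = None         # None => boolean / categorical
    low_label: str = ""
    high_label: str = ""


TABLE_STRATA: tuple[StratumSpec, ...] = (
    StratumSpec("sex", "Sex", None, "male", "female"),
    StratumSpec("weight_kg", "Body weight (kg)", 50.0, "<50", ">=50"),
    StratumSpec("pipc_tazo", "Piperacillin/tazobactam", None, "with", "without"),
    StratumSpec("alb_g_dl", "Alb (g/dL)", 2.5, "<2.5", ">=2.5"),
    StratumSpec("scr_mg_dl", "Scr (mg/dL)", 0.6, "<0.6", ">=0.6"),
    StratumSpec("ccr_ml_min", "Ccr (mL/min)", 30.0, "<30", ">=30"),
    StratumSpec("icu_admission", "ICU admission", None, "with", "without"),
)


def _value_of(patient: Patient, variable: str):
    if variable == "ccr_ml_min":
        from .renal import cockcroft_gault
        return cockcroft_gault(patient.age, patient.weight_kg, patient.scr_mg_dl, patient.sex)
    if not hasattr(patient, variable):
        raise KeyError(f"patient {patient.id}: unknown stratification variable {variable!r}")
    value = getattr(patient, variable)
    if value is None:
        raise KeyError(f"patient {patient.id}: stratification variable {variable!r} missing")
    return value


def stratify(cohort: Sequence[Patient], spec: StratumSpec) -> tuple[list[Patient], list[Patient]]:
    """Split a cohort into the two strata of ``spec`` (a partition)."""
    first: list[Patient] = []
    second: list[Patient] = []
    for p in cohort:
        v = _value_of(p, spec.variable)
        if spec.cutoff is not None:
            (first if float(v) < spec.cutoff else second).append(p)
        elif spec.variable == "sex":
            (first if v == "male" else second).append(p)
        else:
            (first if bool(v) else second).append(p)
    return first, second


def _stratum_masks(df: pd.DataFrame, spec: StratumSpec) -> tuple[np.ndarray, np.ndarray]:
    col = df[spec.variable]
    if spec.cutoff is not None:
        low = col.to_numpy(dtype=float) < spec.cutoff
        return low, ~low
    if spec.variable == "sex":
        male = (col == "male").to_numpy()
        return male, ~male
    flag = col.to_numpy(dtype=bool)
    return flag, ~flag


def _row(variable: str, stratum: str, pred: np.ndarray, meas: np.ndarray, level: float) -> dict:
    n = pred.size
    if n == 0:
        return {
            "variable": variable, "stratum": stratum, "n": 0,
            "me": math.nan, "me_ci_low": math.nan, "me_ci_high": math.nan,
            "me_excludes_zero": None,
            "mae": math.nan, "mae_ci_low": math.nan, "mae_ci_high": math.nan,
        }
    me = mean_error(pred, meas, level)
    mae = mean_absolute_error(pred, meas, level)
    return {
        "variable": variable, "stratum": stratum, "n": n,
        "me": me.value, "me_ci_low": me.ci_low, "me_ci_high": me.ci_high,
        "me_excludes_zero": me.excludes_zero,
        "mae": mae.value, "mae_ci_low": mae.ci_low, "mae_ci_high": mae.ci_high,
    }


REQUIRED_TABLE_COLUMNS = (
    "sex", "weight_kg", "pipc_tazo", "alb_g_dl", "scr_mg_dl",
    "ccr_ml_min", "icu_admission", "predicted", "measured",
)


def accuracy_table(df: pd.DataFrame, level: float = 0.95) -> pd.DataFrame:
    """Stratified ME / MAE report (15 rows: Total + 7 variables x 2 strata).

    ``df`` holds one row per analysed patient with the columns in
    :data:`REQUIRED_TABLE_COLUMNS`. Strata with n = 0 are retained with
    undefined statistics; strata with n = 1 report the point estimate with
    an undefined CI.
    """
    missing = [c for c in REQUIRED_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"accuracy table input is missing column(s): {', '.join(missing)}")
    if df["predicted"].isna().any() or df["measured"].isna().any():
        raise ValueError("every patient needs both a predicted and a measured concentration")
    pred = df["predicted"].to_numpy(dtype=float)
    meas = df["measured"].to_numpy(dtype=float)
    rows = [_row("Total", "", pred, meas, level)]
    for spec in TABLE_STRATA:
        m1, m2 = _stratum_masks(df, spec)
        rows.append(_row(spec.label, spec.low_label, pred[m1], meas[m1], level))
        rows.append(_row(spec.label, spec.high_label, pred[m2], meas[m2], level))
    return pd.DataFrame(rows)
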