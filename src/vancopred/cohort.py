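"""Patient-course data model, cohort table I/O, and exclusion screening.

A cohort is a list of :class:`Patient` records, one per vancomycin course,
read from / written to a delimited text table (comma by default, tab
accepted). Dosing history travels in a compact per-row string:

    ``1000mg@0hx1h;1000mg@12hx1h``        (amount @ start x duration)

and the within-course creatinine series as ``time:value`` pairs:

    ``0:0.8;48:1.2``

Exclusion screening mirrors a retrospective TDM study design in patients
aged >= 75: short courses (<= 3 days), death during the course or within 30
days (precomputed flag), hemodialysis, acute kidney injury during the course
(Scr rise >= 0.3 mg/dL or >= 50% over the first value, KDIGO-style), and
absent trough measurement. Each excluded record carries every reason code
that applies.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd

__all__ = [
    "Dose",
    "Regimen",
    "Patient",
    "ExclusionReason",
    "read_cohort",
    "write_cohort",
    "apply_exclusions",
    "encode_doses",
    "parse_doses",
    "encode_scr_series",
    "parse_scr_series",
]


class Dose(NamedTuple):
    """One intravenous infusion: amount (mg), start and duration (h from course start)."""

    amount_mg: float
    start_h: float
    duration_h: float


@dataclass
class Regimen:
    """Ordered infusion schedule plus the trough sampling time.

    ``sample_time_h`` is the time (h from course start) of the measured /
    predicted trough; by convention it coincides with the start of a
    scheduled dose (trough = immediately pre-dose) but any explicit time is
    accepted.
    """

    doses: list[Dose]
    sample_time_h: float | None = None

    def validate(self) -> None:
        if not self.doses:
            raise ValueError("regimen must contain at least one dose")
        prev = -math.inf
        for i, d in enumerate(self.doses):
            if d.amount_mg <= 0:
                raise ValueError(f"dose {i}: amount must be positive, got {d.amount_mg}")
            if d.duration_h <= 0:
                raise ValueError(f"dose {i}: duration must be positive, got {d.duration_h}")
            if d.start_h <= prev:
                raise ValueError("dose starts must be strictly increasing")
            prev = d.start_h


@dataclass
class Patient:
    """One patient-course: demographics, labs, flags, dosing, measured trough."""

    id: str
    age: float                      # years, >= 75 in the analysis population
    sex: str                        # "male" | "female"
    weight_kg: float
    scr_mg_dl: float                # raw (unrounded) serum creatinine
    alb_g_dl: float
    icu_admission: bool
    pipc_tazo: bool
    on_hemodialysis: bool
    died_within_30d: bool
    course_days: int                # calendar days with >= 1 dose
    scr_series: list[tuple[float, float]] = field(default_factory=list)
    regimen: Regimen | None = None
    measured_trough: float | None = None  # ug/mL

    def validate(self) -> None:
        if self.age < 75:
            raise ValueError(
                f"patient {self.id}: age {self.age} below the 75-year study threshold"
            )
        if self.weight_kg <= 0:
            raise ValueError(f"patient {self.id}: weight must be positive")
        if self.scr_mg_dl <= 0:
            raise ValueError(f"patient {self.id}: Scr must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"patient {self.id}: sex must be 'male' or 'female'")
        if self.measured_trough is not None and self.measured_trough <= 0:
            raise ValueError(f"patient {self.id}: measured trough must be positive")
        if self.scr_series:
            t0, v0 = self.scr_series[0]
            if abs(v0 - self.scr_mg_dl) > 1e-9:
                raise ValueError(
                    f"patient {self.id}: scr ({self.scr_mg_dl}) must equal the first "
                    f"scr_series value ({v0})"
                )
        if self.regimen is not None:
            self.regimen.validate()


class ExclusionReason:
    """Machine-readable exclusion reason codes."""

    SHORT_COURSE = "short_course"       # administration period <= 3 days
    DEATH = "death"                     # died during course or within 30 days
    HEMODIALYSIS = "hemodialysis"
    AKI = "aki"                         # Scr rise >= 0.3 mg/dL or >= 50% over baseline
    NO_MEASUREMENT = "no_measurement"   # no trough concentration measured

    ALL = (SHORT_COURSE, DEATH, HEMODIALYSIS, AKI, NO_MEASUREMENT)


# ---------------------------------------------------------------------------
# compact string encodings

_DOSE_RE = re.compile(
    r"^\s*([0-9]*\.?[0-9]+)\s*mg\s*@\s*([0-9]*\.?[0-9]+)\s*h\s*x\s*([0-9]*\.?[0-9]+)\s*h\s*$"
)


def _fmt(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(x))


def encode_doses(doses: Sequence[Dose]) -> str:
    return ";".join(f"{_fmt(d.amount_mg)}mg@{_fmt(d.start_h)}hx{_fmt(d.duration_h)}h" for d in doses)


def parse_doses(text: str) -> list[Dose]:
    doses = []
    for item in str(text).split(";"):
        m = _DOSE_RE.match(item)
        if m is None:
            raise ValueError(f"malformed dose item {item!r}; expected 'AMOUNTmg@STARThxDURATIONh'")
        doses.append(Dose(float(m.group(1)), float(m.group(2)), float(m.group(3))))
    return doses


def encode_scr_series(series: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{_fmt(t)}:{_fmt(v)}" for t, v in series)


def parse_scr_series(text: str) -> list[tuple[float, float]]:
    out = []
    for item in str(text).split(";"):
        t, _, v = item.partition(":")
        if not _:
            raise ValueError(f"malformed Scr series item {item!r}; expected 'TIME:VALUE'")
        out.append((float(t), float(v)))
    return out


# ---------------------------------------------------------------------------
# table I/O

_COLUMNS = [
    "id", "age", "sex", "weight_kg", "scr_mg_dl", "alb_g_dl",
    "icu_admission", "pipc_tazo", "on_hemodialysis", "died_within_30d",
    "course_days", "scr_series", "regimen", "sample_time_h", "measured_trough",
]

_NUMERIC_COLUMNS = ("age", "weight_kg", "scr_mg_dl", "alb_g_dl")

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(value, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE and s != "":
        return False
    raise ValueError(f"row {row}: cannot parse boolean column {column!r} from {value!r}")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or str(value).strip() == ""


def read_cohort(
    path: str | Path,
    sep: str | None = None,
    column_map: dict[str, str] | None = None,
    validate: bool = True,
) -> list[Patient]:
    """Read a cohort table into a list of :class:`Patient`.

    Parameters
    ----------
    path : delimited text file with a mandatory header row.
    sep : field separator; autodetected between comma and tab when ``None``.
    column_map : optional mapping of *file* column names to the canonical
        ones (``id, age, sex, weight_kg, scr_mg_dl, alb_g_dl, icu_admission,
        pipc_tazo, on_hemodialysis, died_within_30d, course_days, scr_series,
        regimen, sample_time_h, measured_trough``).
    """
    path = Path(path)
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing mandatory column(s): {', '.join(missing)}")

    patients: list[Patient] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, row))
        numeric: dict[str, float] = {}
        for col in _NUMERIC_COLUMNS:
            raw = rec[col]
            if _is_missing(raw):
                raise ValueError(f"row {row_idx}: column {col!r} is empty")
            try:
                numeric[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"row {row_idx}: column {col!r} is not numeric: {raw!r}"
                ) from None
        regimen = Regimen(
            doses=parse_doses(rec["regimen"]),
            sample_time_h=None if _is_missing(rec["sample_time_h"]) else float(rec["sample_time_h"]),
        )
        patient = Patient(
            id=str(rec["id"]),
            age=numeric["age"],
            sex=str(rec["sex"]).strip().lower(),
            weight_kg=numeric["weight_kg"],
            scr_mg_dl=numeric["scr_mg_dl"],
            alb_g_dl=numeric["alb_g_dl"],
            icu_admission=_parse_bool(rec["icu_admission"], "icu_admission", row_idx),
            pipc_tazo=_parse_bool(rec["pipc_tazo"], "pipc_tazo", row_idx),
            on_hemodialysis=_parse_bool(rec["on_hemodialysis"], "on_hemodialysis", row_idx),
            died_within_30d=_parse_bool(rec["died_within_30d"], "died_within_30d", row_idx),
            course_days=int(float(rec["course_days"])),
            scr_series=parse_scr_series(rec["scr_series"]),
            regimen=regimen,
            measured_trough=None if _is_missing(rec["measured_trough"]) else float(rec["measured_trough"]),
        )
        if validate:
            patient.validate()
        patients.append(patient)
    return patients


def write_cohort(cohort: Sequence[Patient], path: str | Path, sep: str = ",") -> None:
    """Write a cohort to a delimited text table (lossless round-trip with read_cohort)."""
    rows = []
    for p in cohort:
        if p.regimen is None:
            raise ValueError(f"patient {p.id}: cannot write a cohort row without a regimen")
        rows.append({
            "id": p.id,
            "age": _fmt(p.age),
            "sex": p.sex,
            "weight_kg": _fmt(p.weight_kg),
            "scr_mg_dl": _fmt(p.scr_mg_dl),
            "alb_g_dl": _fmt(p.alb_g_dl),
            "icu_admission": str(p.icu_admission).lower(),
            "pipc_tazo": str(p.pipc_tazo).lower(),
            "on_hemodialysis": str(p.on_hemodialysis).lower(),
            "died_within_30d": str(p.died_within_30d).lower(),
            "course_days": str(p.course_days),
            "scr_series": encode_scr_series(p.scr_series),
            "regimen": encode_doses(p.regimen.doses),
            "sample_time_h": "" if p.regimen.sample_time_h is None else _fmt(p.regimen.sample_time_h),
            "measured_trough": "" if p.measured_trough is None else repr(p.measured_trough),
        })
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# exclusion screening

AKI_ABSOLUTE_RISE_MG_DL = 0.3
AKI_RELATIVE_RISE = 1.5


def has_aki(scr_series: Sequence[tuple[float, float]]) -> bool:
    """Scr rise >= 0.3 mg/dL absolute or >= 50% over the course-start value.

    The baseline is the first value of the series; the series must be
    non-empty.
    """
    if not scr_series:
        raise ValueError("cannot evaluate AKI on an empty Scr series")
    baseline = scr_series[0][1]
    for _, v in scr_series[1:]:
        if v >= baseline + AKI_ABSOLUTE_RISE_MG_DL or v >= AKI_RELATIVE_RISE * baseline:
            return True
    return False


def exclusion_reasons(patient: Patient) -> tuple[str, ...]:
    """All exclusion reason codes that apply to one patient (possibly none)."""
    reasons = []
    if patient.course_days <= 3:
        reasons.append(ExclusionReason.SHORT_COURSE)
    if patient.died_within_30d:
        reasons.append(ExclusionReason.DEATH)
    if patient.on_hemodialysis:
        reasons.append(ExclusionReason.HEMODIALYSIS)
    if has_aki(patient.scr_series):
        reasons.append(ExclusionReason.AKI)
    if patient.measured_trough is None:
        reasons.append(ExclusionReason.NO_MEASUREMENT)
    return tuple(reasons)


def apply_exclusions(
    cohort: Sequence[Patient],
) -> tuple[list[Patient], list[tuple[Patient, tuple[str, ...]]]]:
    """Partition a cohort into the analysis set and excluded records.

    Returns ``(included, excluded)`` where each excluded entry is
    ``(patient, reason_codes)`` with every applicable code. The two sides
    partition the input: each patient appears exactly once.
    """
    included: list[Patient] = []
    excluded: list[tuple[Patient, tuple[str, ...]]] = []
    for p in cohort:
        reasons = exclusion_reasons(p)
        if reasons:
            excluded.append((p, reasons))
        else:
            included.append(p)
    return included, excluded
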