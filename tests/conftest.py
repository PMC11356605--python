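"""Shared fixtures: programmatic patient/cohort factories (no data files)."""

from __future__ import annotations

import pytest

from vancopred.cohort import Dose, Patient, Regimen


def make_regimen(amount=1000.0, interval=12.0, n_doses=7, duration=1.0, sample_time=None):
    doses = [Dose(amount, interval * i, duration) for i in range(n_doses)]
    if sample_time is None:
        sample_time = interval * (n_doses - 1)
    return Regimen(doses=doses, sample_time_h=sample_time)


def make_patient(**overrides) -> Patient:
    base = dict(
        id="P-01",
        age=80.0,
        sex="male",
        weight_kg=50.0,
        scr_mg_dl=1.0,
        alb_g_dl=3.0,
        icu_admission=False,
        pipc_tazo=False,
        on_hemodialysis=False,
        died_within_30d=False,
        course_days=7,
        scr_series=None,
        regimen=None,
        measured_trough=10.0,
    )
    base.update(overrides)
    if base["scr_series"] is None:
        base["scr_series"] = [(0.0, base["scr_mg_dl"]), (48.0, base["scr_mg_dl"])]
    if base["regimen"] is None:
        base["regimen"] = make_regimen()
    return Patient(**base)


@pytest.fixture
def patient():
    return make_patient()


@pytest.fixture
def small_cohort():
    """Six clean patients spanning both sides of every stratification cutoff."""
    return [
        make_patient(id="A", sex="male", weight_kg=45.0, alb_g_dl=2.0, scr_mg_dl=0.5,
                     measured_trough=9.0),
        make_patient(id="B", sex="female", weight_kg=55.0, alb_g_dl=3.0, scr_mg_dl=1.2,
                     measured_trough=11.0),
        make_patient(id="C", sex="male", weight_kg=50.0, alb_g_dl=2.5, scr_mg_dl=0.6,
                     measured_trough=8.0),
        make_patient(id="D", sex="female", weight_kg=38.0, alb_g_dl=1.8, scr_mg_dl=0.4,
                     icu_admission=True, measured_trough=6.5),
        make_patient(id="E", sex="male", weight_kg=62.0, alb_g_dl=3.4, scr_mg_dl=2.5,
                     pipc_tazo=True, measured_trough=14.0),
        make_patient(id="F", sex="female", weight_kg=47.0, alb_g_dl=2.4, scr_mg_dl=0.9,
                     measured_trough=10.0),
    ]
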