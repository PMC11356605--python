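"""ME/MAE, Bland-Altman and stratification against hand-computed oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_patient
from vancopred.stats import (
    TABLE_STRATA,
    StratumSpec,
    accuracy_table,
    bland_altman,
    mean_absolute_error,
    mean_error,
    stratify,
)

# worked 3-pair example: differences (1, 2, -1), sd 1.527525, t(0.975, 2) = 4.302653
PRED3 = np.array([10.0, 12.0, 8.0])
MEAS3 = np.array([9.0, 10.0, 9.0])


class TestMeanError:
    def test_hand_oracle(self):
        me = mean_error(PRED3, MEAS3)
        assert me.value == pytest.approx(2 / 3, abs=1e-12)
        assert me.ci_low == pytest.approx(-3.127916366930093, abs=1e-9)
        assert me.ci_high == pytest.approx(4.461249700263426, abs=1e-9)
        assert me.excludes_zero is False

    def test_perfect_prediction(self):
        me = mean_error([5.0, 7.0], [5.0, 7.0])
        assert me.value == 0.0 and me.ci_low == 0.0 and me.ci_high == 0.0

    def test_sign_flip_mirrors_interval(self):
        me = mean_error(PRED3, MEAS3)
        flipped = mean_error(MEAS3, PRED3)
        assert flipped.value == pytest.approx(-me.value, abs=1e-12)
        assert flipped.ci_low == pytest.approx(-me.ci_high, abs=1e-12)
        assert flipped.ci_high == pytest.approx(-me.ci_low, abs=1e-12)

    def test_single_pair_has_undefined_ci(self):
        me = mean_error([10.0], [8.0])
        assert me.value == 2.0 and not me.ci_defined and me.excludes_zero is None

    def test_errors(self):
        with pytest.raises(ValueError):
            mean_error([], [])
        with pytest.raises(ValueError):
            mean_error([1.0, 2.0], [1.0])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=30))
    def test_permutation_invariance(self, diffs):
        meas = np.full(len(diffs), 10.0)
        pred = meas + np.array(diffs)
        base = mean_error(pred, meas)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(diffs))
        shuffled = mean_error(pred[perm], meas[perm])
        assert shuffled.value == pytest.approx(base.value, abs=1e-12)
        assert shuffled.ci_low == pytest.approx(base.ci_low, abs=1e-9)


class TestMeanAbsoluteError:
    def test_hand_oracle(self):
        mae = mean_absolute_error(PRED3, MEAS3)
        assert mae.value == pytest.approx(4 / 3, abs=1e-12)

    def test_zero_for_perfect_prediction(self):
        assert mean_absolute_error([5.0, 7.0], [5.0, 7.0]).value == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=30))
    def test_mae_dominates_absolute_me(self, diffs):
        meas = np.full(len(diffs), 10.0)
        pred = meas + np.array(diffs)
        assert mean_absolute_error(pred, meas).value >= abs(mean_error(pred, meas).value) - 1e-12


class TestBlandAltman:
    def test_hand_oracle(self):
        ba = bland_altman(PRED3, MEAS3)
        assert ba.bias == pytest.approx(2 / 3, abs=1e-12)
        assert ba.loa_lower == pytest.approx(-2.3272827873711486, abs=1e-9)
        assert ba.loa_upper == pytest.approx(3.6606161207044816, abs=1e-9)

    def test_identical_vectors(self):
        ba = bland_altman([4.0, 6.0, 9.0], [4.0, 6.0, 9.0])
        assert ba.bias == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_midpoint_of_loa_is_bias(self):
        rng = np.random.default_rng(3)
        pred, meas = rng.uniform(3, 25, 80), rng.uniform(3, 25, 80)
        ba = bland_altman(pred, meas)
        assert (ba.loa_upper + ba.loa_lower) / 2 == pytest.approx(ba.bias, abs=1e-12)

    def test_bias_equals_mean_error(self):
        assert bland_altman(PRED3, MEAS3).bias == mean_error(PRED3, MEAS3).value

    def test_points_are_average_difference_pairs(self):
        ba = bland_altman(PRED3, MEAS3)
        np.testing.assert_allclose(ba.averages, (PRED3 + MEAS3) / 2)
        np.testing.assert_allclose(ba.differences, PRED3 - MEAS3)

    def test_normal_differences_land_inside_loa_95pct(self):
        rng = np.random.default_rng(11)
        n = 10_000
        meas = rng.uniform(5, 20, n)
        pred = meas + rng.normal(0.5, 2.0, n)
        ba = bland_altman(pred, meas)
        assert ba.frac_within_loa == pytest.approx(0.95, abs=0.01)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([10.0], [9.0])


class TestStratify:
    def test_boundary_value_goes_to_upper_stratum(self):
        spec = StratumSpec("weight_kg", "Body weight (kg)", 50.0, "<50", ">=50")
        cohort = [make_patient(id="L", weight_kg=49.9), make_patient(id="B", weight_kg=50.0)]
        low, high = stratify(cohort, spec)
        assert [p.id for p in low] == ["L"] and [p.id for p in high] == ["B"]

    def test_partition(self, small_cohort):
        for spec in TABLE_STRATA:
            a, b = stratify(small_cohort, spec)
            assert len(a) + len(b) == len(small_cohort)
            assert {p.id for p in a} | {p.id for p in b} == {p.id for p in small_cohort}

    def test_all_below_cutoff_leaves_empty_stratum(self):
        spec = StratumSpec("alb_g_dl", "Alb (g/dL)", 2.5, "<2.5", ">=2.5")
        cohort = [make_patient(id=str(i), alb_g_dl=2.0) for i in range(3)]
        low, high = stratify(cohort, spec)
        assert len(low) == 3 and high == []

    def test_unknown_variable_names_patient(self):
        with pytest.raises(KeyError, match="P-01"):
            stratify([make_patient()], StratumSpec("bmi", "BMI", 20.0))


def _table_frame(patients, pred, meas):
    from vancopred.renal import cockcroft_gault
    return pd.DataFrame({
        "sex": [p.sex for p in patients],
        "weight_kg": [p.weight_kg for p in patients],
        "pipc_tazo": [p.pipc_tazo for p in patients],
        "alb_g_dl": [p.alb_g_dl for p in patients],
        "scr_mg_dl": [p.scr_mg_dl for p in patients],
        "ccr_ml_min": [cockcroft_gault(p.age, p.weight_kg, p.scr_mg_dl, p.sex) for p in patients],
        "icu_admission": [p.icu_admission for p in patients],
        "predicted": pred,
        "measured": meas,
    })


class TestAccuracyTable:
    def test_layout_has_15_rows(self, small_cohort):
        df = _table_frame(small_cohort, [10.0] * 6, [9.0] * 6)
        table = accuracy_table(df)
        assert len(table) == 15
        assert table.iloc[0]["variable"] == "Total" and table.iloc[0]["n"] == 6

    def test_perfect_predictions_give_all_zero_rows(self, small_cohort):
        meas = [9.0, 11.0, 8.0, 6.5, 14.0, 10.0]
        table = accuracy_table(_table_frame(small_cohort, meas, meas))
        populated = table[table["n"] > 0]
        assert (populated["me"] == 0.0).all() and (populated["mae"] == 0.0).all()

    def test_stratum_rows_match_direct_computation(self, small_cohort):
        pred = np.array([10.0, 12.0, 8.0, 7.0, 15.5, 9.0])
        meas = np.array([9.0, 11.0, 8.0, 6.5, 14.0, 10.0])
        table = accuracy_table(_table_frame(small_cohort, pred, meas))
        # male patients are A, C, E (indices 0, 2, 4)
        male = table[(table.variable == "Sex") & (table.stratum == "male")].iloc[0]
        idx = [0, 2, 4]
        me = mean_error(pred[idx], meas[idx])
        assert male["n"] == 3
        assert male["me"] == pytest.approx(me.value, abs=1e-12)
        assert male["me_ci_low"] == pytest.approx(me.ci_low, abs=1e-12)
        mae = mean_absolute_error(pred[idx], meas[idx])
        assert male["mae"] == pytest.approx(mae.value, abs=1e-12)
        # weight boundary: patient C (50.0 kg) sits in the >=50 stratum
        ge50 = table[(table.variable == "Body weight (kg)") & (table.stratum == ">=50")].iloc[0]
        assert ge50["n"] == 3  # B (55), C (50), E (62)

    def test_empty_stratum_row_retained_with_nan(self, small_cohort):
        cohort = [make_patient(id=str(i), icu_admission=False) for i in range(4)]
        table = accuracy_table(_table_frame(cohort, [10.0] * 4, [9.0] * 4))
        icu = table[(table.variable == "ICU admission") & (table.stratum == "with")].iloc[0]
        assert icu["n"] == 0 and math.isnan(icu["me"]) and math.isnan(icu["mae"])

    def test_total_row_equals_union_of_any_split(self, small_cohort):
        pred = np.array([10.0, 12.0, 8.0, 7.0, 15.5, 9.0])
        meas = np.array([9.0, 11.0, 8.0, 6.5, 14.0, 10.0])
        table = accuracy_table(_table_frame(small_cohort, pred, meas))
        total = table.iloc[0]
        for variable in table["variable"].unique()[1:]:
            pair = table[table.variable == variable]
            assert pair["n"].sum() == total["n"]

    def test_missing_measurement_rejected(self, small_cohort):
        df = _table_frame(small_cohort, [10.0] * 6, [9.0] * 5 + [np.nan])
        with pytest.raises(ValueError):
            accuracy_table(df)
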