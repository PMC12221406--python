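"""Clinical derivations: BATT, SMM equations, sarcopenia classification, I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarcnet.cohort import (
    DEFAULT_CUTOFFS,
    MeasurementPanel,
    ParticipantRecord,
    classify_sarcopenia,
    cohort_to_frame,
    compute_batt,
    estimate_smm_janssen,
    estimate_smm_sergi,
    frame_to_cohort,
    read_cohort_csv,
    write_cohort_csv,
)


class TestBatt:
    @pytest.mark.parametrize("thicknesses,expected", [
        ((0, 0, 0, 0), 0.0),
        ((1.2, 1.0, 1.3, 0.9), 4.4),
        ((1.0, 0.9, 1.0, 0.9), 3.8),
    ])
    def test_sum_of_four_thicknesses(self, thicknesses, expected):
        assert compute_batt(*thicknesses) == pytest.approx(expected)

    def test_3_8_cm_is_low_for_a_female(self):
        assert compute_batt(1.0, 0.9, 1.0, 0.9) < DEFAULT_CUTOFFS.batt_low["female"]

    @pytest.mark.parametrize("bad", [
        (None, 1.0, 1.0, 1.0),
        (float("nan"), 1.0, 1.0, 1.0),
        (-0.1, 1.0, 1.0, 1.0),
    ])
    def test_missing_or_negative_propagates_as_nan(self, bad):
        assert math.isnan(compute_batt(*bad))

    @given(st.permutations([0.7, 1.1, 1.3, 0.4]))
    def test_permutation_invariant(self, perm):
        assert compute_batt(*perm) == pytest.approx(compute_batt(0.7, 1.1, 1.3, 0.4))

    @given(st.lists(st.floats(0, 5, allow_nan=False), min_size=4, max_size=4),
           st.lists(st.floats(0, 5, allow_nan=False), min_size=4, max_size=4))
    @settings(max_examples=50)
    def test_additive(self, a, b):
        total = compute_batt(*(x + y for x, y in zip(a, b)))
        assert total == pytest.approx(compute_batt(*a) + compute_batt(*b), abs=1e-9)


class TestSmmEquations:
    def test_sergi_worked_example(self):
        assert estimate_smm_sergi(170, 70, 500, 50, "male") == pytest.approx(20.39, abs=0.01)
        assert estimate_smm_sergi(170, 70, 500, 50, "female") == pytest.approx(19.01, abs=0.01)

    def test_sergi_sex_term(self):
        m = estimate_smm_sergi(170, 70, 500, 50, "male")
        f = estimate_smm_sergi(170, 70, 500, 50, "female")
        assert m - f == pytest.approx(1.384, abs=1e-9)

    def test_janssen_worked_example(self):
        assert estimate_smm_janssen(170, 500, "male", 80) == pytest.approx(26.42, abs=0.01)
        assert estimate_smm_janssen(170, 500, "female", 80) == pytest.approx(22.60, abs=0.01)

    def test_janssen_linear_in_age(self):
        a80 = estimate_smm_janssen(170, 500, "male", 80)
        a81 = estimate_smm_janssen(170, 500, "male", 81)
        assert a81 - a80 == pytest.approx(-0.071, abs=1e-9)

    @pytest.mark.parametrize("resistance", [0.0, -10.0])
    def test_nonpositive_resistance_is_missing(self, resistance):
        assert math.isnan(estimate_smm_sergi(170, 70, resistance, 50, "male"))
        assert math.isnan(estimate_smm_janssen(170, resistance, "male", 80))

    def test_coefficients_by_finite_differences(self):
        # both estimators are affine in each argument
        base = (170.0, 70.0, 500.0, 50.0)
        f0 = estimate_smm_sergi(*base, "female")
        assert estimate_smm_sergi(170, 71, 500, 50, "female") - f0 == pytest.approx(0.095)
        assert estimate_smm_sergi(170, 70, 500, 51, "female") - f0 == pytest.approx(0.064)
        ht2r0 = 170.0**2 / 500.0
        f_r = estimate_smm_sergi(170, 70, 400, 50, "female")
        assert f_r - f0 == pytest.approx(0.227 * (170**2 / 400 - ht2r0))
        j0 = estimate_smm_janssen(170, 500, "female", 80)
        j_r = estimate_smm_janssen(170, 400, "female", 80)
        assert j_r - j0 == pytest.approx(0.401 * (170**2 / 400 - ht2r0))


class TestClassification:
    @pytest.mark.parametrize("sex,hgs,batt,smm,expected", [
        ("female", 15, 3.5, 16, "present"),
        ("male", 30, 3.0, 10, "absent"),        # non-low strength dominates
        ("female", 15, 4.0, 14, "present"),     # SMM arm alone suffices
        ("male", 26, 5.0, 21, "present"),       # BATT arm alone suffices
        ("female", 15, 4.0, 16, "absent"),      # strength low, quantity normal
    ])
    def test_definition(self, sex, hgs, batt, smm, expected):
        assert classify_sarcopenia(hgs, batt, smm, sex) == expected

    @pytest.mark.parametrize("sex,cut", [("female", 16.0), ("male", 27.0)])
    def test_handgrip_cutoff_is_strict(self, sex, cut):
        # exactly at the cutoff is NOT low; just below is
        assert classify_sarcopenia(cut, 1.0, 1.0, sex) == "absent"
        assert classify_sarcopenia(cut - 1e-9, 1.0, 1.0, sex) == "present"

    @pytest.mark.parametrize("sex,cut", [("female", 3.85), ("male", 5.44)])
    def test_batt_cutoff_is_strict(self, sex, cut):
        assert classify_sarcopenia(1.0, cut, 99.0, sex) == "absent"
        assert classify_sarcopenia(1.0, cut - 1e-9, 99.0, sex) == "present"

    @pytest.mark.parametrize("sex,cut", [("female", 15.0), ("male", 20.0)])
    def test_smm_cutoff_is_strict(self, sex, cut):
        assert classify_sarcopenia(1.0, 99.0, cut, sex) == "absent"
        assert classify_sarcopenia(1.0, 99.0, cut - 1e-9, sex) == "present"

    def test_missing_value_adjudication(self):
        nan = float("nan")
        assert classify_sarcopenia(nan, 3.0, 10, "female") == "indeterminate"
        # strength low, one quantity arm missing, observed arm non-low:
        # the missing arm could still flip the call
        assert classify_sarcopenia(15, nan, 16, "female") == "indeterminate"
        assert classify_sarcopenia(15, 4.0, nan, "female") == "indeterminate"
        # an observed low arm settles it regardless of the other
        assert classify_sarcopenia(15, nan, 14, "female") == "present"
        assert classify_sarcopenia(15, 3.0, nan, "female") == "present"
        # non-low strength settles it with everything else missing
        assert classify_sarcopenia(20, nan, nan, "female") == "absent"
        assert classify_sarcopenia(15, nan, nan, "female") == "indeterminate"

    @given(st.sampled_from(["female", "male"]),
           st.floats(0, 60, allow_nan=False), st.floats(0, 12, allow_nan=False),
           st.floats(0, 40, allow_nan=False),
           st.floats(0.1, 10), st.floats(0.1, 3), st.floats(0.1, 10))
    @settings(max_examples=200)
    def test_monotone_in_all_measures(self, sex, hgs, batt, smm, d1, d2, d3):
        """Decreasing any measurement never turns present into absent."""
        before = classify_sarcopenia(hgs, batt, smm, sex)
        after = classify_sarcopenia(max(hgs - d1, 0), max(batt - d2, 0),
                                    max(smm - d3, 0), sex)
        if before == "present":
            assert after == "present"


class TestRecordsAndIO:
    def test_record_validation(self):
        with pytest.raises(ValueError, match="age"):
            ParticipantRecord(id="a", group="medical", sex="female", age=69)
        with pytest.raises(ValueError, match="flag"):
            ParticipantRecord(id="a", group="medical", sex="female", age=80,
                              condition_flags={"COPD": 2})
        with pytest.raises(ValueError, match="preoperative"):
            ParticipantRecord(id="a", group="medical", sex="female", age=80,
                              panels={"preop": MeasurementPanel()})

    def test_panel_validation(self):
        with pytest.raises(ValueError, match="echogenicity"):
            MeasurementPanel(echogenicity_gsu=300.0)
        with pytest.raises(ValueError, match=">= 0"):
            MeasurementPanel(handgrip_kg=-1.0)

    def test_frame_record_round_trip(self, tiny_frame):
        records = frame_to_cohort(tiny_frame)
        back = cohort_to_frame(records)
        a = tiny_frame.sort_values(["participant_id", "timepoint"]).reset_index(drop=True)
        b = back.sort_values(["participant_id", "timepoint"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[sorted(a.columns)], b[sorted(b.columns)],
                                      check_dtype=False)

    def test_csv_round_trip(self, tiny_frame, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort_csv(tiny_frame, path)
        assert (tmp_path / "cohort.csv.schema.json").exists()
        frame = read_cohort_csv(path, compute_status=False)
        pd.testing.assert_frame_equal(
            tiny_frame.reset_index(drop=True), frame, check_dtype=False)

    def test_reader_classifies_missing_status(self, tmp_path, tiny_frame):
        frame = tiny_frame.drop(columns=["sarc_status"])
        path = tmp_path / "nostatus.csv"
        frame.to_csv(path, index=False)
        out = read_cohort_csv(path)
        assert "sarc_status" in out.columns
        # every filled status is a valid binary call
        filled = out["sarc_status"].dropna()
        assert set(filled.unique()) <= {0.0, 1.0}

    def test_checked_in_fixture_matches_generator(self, tiny_frame):
        from conftest import DATA_DIR
        frame = read_cohort_csv(DATA_DIR / "tiny_cohort.csv", compute_status=False)
        pd.testing.assert_frame_equal(
            tiny_frame.reset_index(drop=True), frame, check_dtype=False)
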