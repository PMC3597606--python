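"""Tumor volume, growth-response classification and outcome summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ritdose.outcomes import (
    ApoptosisFieldCounts,
    GrowthRecord,
    TumorMeasurement,
    apoptosis_density,
    apply_censoring,
    arm_summary,
    classify_response,
    compare_apoptosis,
    dose_response_threshold,
    tumor_volume,
)


@pytest.mark.parametrize(
    "dims, expected",
    [((2, 2, 2), 4.0), ((1, 1, 1), 0.5), ((3, 2, 4), 12.0), ((0, 5, 5), 0.0)],
)
def test_tumor_volume(dims, expected):
    w, h, d = dims
    assert tumor_volume(TumorMeasurement("m", 0, w, h, d)) == expected


@given(dims=st.permutations([1.5, 2.5, 4.0]))
def test_tumor_volume_symmetric_in_dimensions(dims):
    w, h, d = dims
    assert tumor_volume(TumorMeasurement("m", 0, w, h, d)) == pytest.approx(7.5)


DAYS = [0, 3, 7, 10, 14, 17, 21, 24, 28]


class TestClassifyResponse:
    def test_strictly_increasing_is_progression(self):
        assert classify_response(DAYS, np.geomspace(4, 100, 9)) == "progression"

    def test_sustained_disappearance_is_complete_regression(self):
        vols = [4, 5, 2, 1.5, 0.0, 0.0, 0.0, 0.0, 0.0]
        assert classify_response(DAYS, vols) == "complete_regression"

    def test_regrowth_after_disappearance(self):
        vols = [4, 5, 2, 1.5, 0.0, 0.5, 5.0, 20.0, 50.0]
        assert classify_response(DAYS, vols) == "regression_with_regrowth"

    def test_transient_shrinkage_is_growth_delay(self):
        vols = [4, 3.5, 3, 2.5, 3, 4, 6, 9, 14]
        assert classify_response(DAYS, vols) == "growth_delay"

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            classify_response([0, 7], [4, 8])

    def test_rescaling_invariance(self):
        vols = np.array([4, 5, 2, 1.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        base = classify_response(DAYS, vols)
        scaled = classify_response(DAYS, vols * 10, disappearance_threshold_mm3=10.0)
        assert base == scaled == "complete_regression"


class TestCensoring:
    def test_censors_at_first_day_over_endpoint(self):
        rec = GrowthRecord("m", "arm", [0, 3, 7, 10, 14], [4, 50, 150, 250, 400])
        out = apply_censoring(rec)
        assert out.censored_day == 10
        assert out.days.tolist() == [0, 3, 7, 10]

    def test_no_censoring_below_endpoint(self):
        rec = GrowthRecord("m", "arm", [0, 3, 7], [4, 8, 16])
        assert apply_censoring(rec).censored_day is None


class TestArmSummary:
    def test_relative_volume(self):
        rec = GrowthRecord("m", "a", [0.0, 7.0], [4.0, 8.0])
        summ = arm_summary([rec])
        assert summ["per_day"]["mean_rel_volume"].tolist() == [1.0, 2.0]

    def test_identical_animals_zero_sd(self):
        recs = [GrowthRecord(f"m{i}", "a", [0.0, 7.0], [4.0, 8.0]) for i in range(5)]
        summ = arm_summary(recs)
        assert summ["per_day"]["sd_rel_volume"].tolist() == [0.0, 0.0]
        assert summ["n_animals"] == 5

    def test_censored_days_excluded_from_later_means(self):
        fast = GrowthRecord("f", "a", [0.0, 7.0, 14.0], [4.0, 300.0, 600.0])
        slow = GrowthRecord("s", "a", [0.0, 7.0, 14.0], [4.0, 8.0, 16.0])
        summ = arm_summary([fast, slow])
        per_day = summ["per_day"].set_index("day")
        assert per_day.loc[14.0, "n"] == 1  # fast animal censored at day 7
        assert per_day.loc[14.0, "mean_rel_volume"] == pytest.approx(4.0)
        assert summ["censored_count"] == 1

    def test_missing_day_zero_errors(self):
        rec = GrowthRecord("m", "a", [3.0, 7.0, 10.0], [4.0, 8.0, 12.0])
        with pytest.raises(ValueError, match="day-0"):
            arm_summary([rec])


class TestDoseResponseThreshold:
    def arms(self):
        cr = ["complete_regression"] * 5
        return (
            {"a042": 4.2, "a105": 10.5, "a210": 21.0, "a180": 18.0, "a359": 35.9},
            {
                "a042": ["progression"] * 5,
                "a105": ["growth_delay"] * 5,
                "a210": cr,
                "a180": cr[:4] + ["regression_with_regrowth"],
                "a359": cr,
            },
        )

    def test_published_arm_pattern_gives_18_gy(self):
        doses, responses = self.arms()
        result = dose_response_threshold(doses, responses, allowed_exceptions=1)
        assert result["threshold_Gy"] == 18.0
        assert result["violations_above_threshold"] == []

    def test_strict_exception_count_moves_threshold(self):
        doses, responses = self.arms()
        result = dose_response_threshold(doses, responses, allowed_exceptions=0)
        assert result["threshold_Gy"] == 21.0

    def test_all_cr_returns_minimum_dose(self):
        doses = {"lo": 5.0, "hi": 20.0}
        responses = {k: ["complete_regression"] * 3 for k in doses}
        assert dose_response_threshold(doses, responses)["threshold_Gy"] == 5.0

    def test_no_qualifying_arm(self):
        doses = {"lo": 5.0}
        responses = {"lo": ["progression"] * 3}
        assert dose_response_threshold(doses, responses)["threshold_Gy"] is None


class TestApoptosis:
    def test_constant_fields(self):
        afc = ApoptosisFieldCounts("a", [10] * 5, [100] * 5)
        out = apoptosis_density(afc)
        assert out["mean_fraction"] == pytest.approx(0.10)
        assert out["sd_fraction"] == 0.0

    def test_all_negative_fields(self):
        out = apoptosis_density(ApoptosisFieldCounts("a", [0] * 5, [100] * 5))
        assert out["mean_fraction"] == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ApoptosisFieldCounts("a", [1] * 4, [10] * 4)  # < 5 fields
        with pytest.raises(ValueError):
            ApoptosisFieldCounts("a", [11] * 5, [10] * 5)  # positives > total
        with pytest.raises(ValueError):
            ApoptosisFieldCounts("a", [0] * 5, [0] * 5)  # zero-cell field

    def test_two_sample_comparison_direction(self):
        lo = ApoptosisFieldCounts("lo", [2, 3, 2, 4, 3], [100] * 5)
        hi = ApoptosisFieldCounts("hi", [30, 28, 35, 31, 29], [100] * 5)
        out = compare_apoptosis(hi, lo)
        assert out["t_statistic"] > 0
        assert out["p_value"] < 0.01
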