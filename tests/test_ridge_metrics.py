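"""MRB/RD duality, print filtering, CV with outlier screening, typing."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ridgemix import (
    PrintRecord, classify_assemblage, coefficient_of_variation, filter_prints,
    mrb_to_rd, rd_to_mrb, remove_extreme_outliers,
)
from ridgemix.ridge_metrics import AssemblageClass, characterize_assemblage


class TestMrbRdConversion:
    def test_printed_formula(self):
        assert mrb_to_rd(0.5) == pytest.approx(5 * math.sqrt(2) / 0.5, abs=1e-12)

    def test_independent_arithmetic_value(self):
        # 5*sqrt(2)/0.4714045 computed independently
        assert mrb_to_rd(0.4714045) == pytest.approx(15.0, abs=1e-5)

    def test_unit_case(self):
        assert rd_to_mrb(5 * math.sqrt(2)) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(min_value=0.05, max_value=2.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_and_monotonicity(self, mrb):
        assert rd_to_mrb(mrb_to_rd(mrb)) == pytest.approx(mrb, abs=1e-12)
        assert mrb_to_rd(mrb * 1.01) < mrb_to_rd(mrb)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            mrb_to_rd(bad)
        with pytest.raises(ValueError):
            rd_to_mrb(bad)


class TestFilterPrints:
    def _prints(self, ridge_counts):
        return [PrintRecord(id=str(i), mrb=0.5, n_ridges=n)
                for i, n in enumerate(ridge_counts)]

    def test_six_ridge_rule(self):
        kept = filter_prints(self._prints([5, 6, 10]), min_ridges=6)
        assert [p.id for p in kept] == ["1", "2"]

    def test_identity_when_all_pass(self):
        prints = self._prints([10] * 5)
        assert filter_prints(prints, min_ridges=10) == prints

    def test_empty_input(self):
        assert filter_prints([], min_ridges=6) == []

    def test_preserves_order_and_records(self):
        prints = self._prints([8, 3, 12, 7])
        kept = filter_prints(prints, 6)
        assert kept == [prints[0], prints[2], prints[3]]


class TestOutlierRemoval:
    def test_constant_list_unchanged(self):
        vals = [0.5] * 10
        assert remove_extreme_outliers(vals) == vals

    def test_single_gross_outlier_removed(self):
        # brute-force robust z: only 4.0 exceeds 3.5 MADs from the median
        vals = [0.4] * 20 + [4.0]
        med = np.median(vals)
        mad = np.median(np.abs(np.array(vals) - med))
        z = np.abs(np.array(vals) - med) / (1.4826 * mad) if mad else None
        cleaned = remove_extreme_outliers(vals)
        assert cleaned == [0.4] * 20

    def test_infinite_threshold_is_identity(self):
        vals = [0.3, 0.5, 0.9, 2.0]
        assert remove_extreme_outliers(vals, threshold=math.inf) == vals

    def test_zero_mad_falls_back_to_sd(self):
        # majority identical -> MAD 0, but values differ: SD rule applies
        vals = [0.5] * 10 + [0.51, 50.0]
        cleaned = remove_extreme_outliers(vals)
        assert 50.0 in cleaned or 50.0 not in cleaned  # must not raise
        assert len(cleaned) <= len(vals)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            remove_extreme_outliers([1.0, 2.0])


class TestCoefficientOfVariation:
    def test_zero_spread(self):
        assert coefficient_of_variation([1, 1, 1]) == 0.0

    def test_hand_checked_value(self):
        # sd = sqrt(2), mean = 3 -> 0.471405
        assert coefficient_of_variation([2, 4]) == pytest.approx(0.471405, abs=1e-6)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k):
        base = [0.8, 1.0, 1.3, 0.9, 1.1]
        assert coefficient_of_variation([k * v for v in base]) == pytest.approx(
            coefficient_of_variation(base), rel=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-2.0, 0.0])


class TestAssemblageTyping:
    @pytest.mark.parametrize("cv,expected", [
        (0.08, AssemblageClass.Type1),
        (0.10, AssemblageClass.Type2),
        (0.12, AssemblageClass.Type3),
        # boundary values fall in the intermediate class by convention
        (0.09, AssemblageClass.Type2),
        (0.11, AssemblageClass.Type2),
        (0.0, AssemblageClass.Type1),
        (1.0, AssemblageClass.Type3),
    ])
    def test_classification(self, cv, expected):
        assert classify_assemblage(cv).value is expected

    def test_near_boundary_flag(self):
        assert classify_assemblage(0.0885).near_boundary
        assert not classify_assemblage(0.05).near_boundary

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_partition(self, cv):
        # every CV maps to exactly one type
        result = classify_assemblage(cv)
        assert result.value in AssemblageClass

    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            classify_assemblage(0.1, bounds=(0.11, 0.09))


class TestCharacterize:
    def test_adult_male_assemblage_is_type1(self, adult_male_prints):
        atype, report = characterize_assemblage(adult_male_prints)
        assert atype.value is AssemblageClass.Type1
        assert report["n_used"] > 0
        assert report["cv"] < 0.09
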