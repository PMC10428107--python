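"""Reference filtering by assemblage type and percentile-alignment scaling."""
import numpy as np
import pytest

from ridgemix import (
    PrintRecord, ReferenceRecord, apply_scaling, coefficient_of_variation,
    compute_scaling_factor, filter_reference_by_type,
)
from ridgemix.ridge_metrics import AssemblageClass, classify_assemblage
from ridgemix.scaling import scale_assemblage
from ridgemix.simulate import Scenario, generate_assemblage


@pytest.fixture
def mixed_reference():
    rows = [
        ReferenceRecord(age=10, sex=1, mrb=0.40),
        ReferenceRecord(age=14, sex=2, mrb=0.47),
        ReferenceRecord(age=16, sex=1, mrb=0.46),
        ReferenceRecord(age=30, sex=2, mrb=0.55),
        ReferenceRecord(age=50, sex=2, mrb=0.56),
        ReferenceRecord(age=40, sex=1, mrb=0.47),
    ]
    return rows


class TestReferenceFiltering:
    def test_type1_keeps_adult_males_only(self, mixed_reference):
        kept = filter_reference_by_type(mixed_reference, AssemblageClass.Type1)
        assert all(r.sex == 2 and r.age >= 15 for r in kept)
        assert len(kept) == 2

    def test_type2_keeps_both_sexes_15_plus(self, mixed_reference):
        kept = filter_reference_by_type(mixed_reference, AssemblageClass.Type2)
        assert all(r.age >= 15 for r in kept)
        # the 14-year-old male is excluded
        assert not any(r.age == 14 for r in kept)
        assert len(kept) == 4

    def test_type3_is_identity(self, mixed_reference):
        kept = filter_reference_by_type(mixed_reference, AssemblageClass.Type3)
        assert kept == mixed_reference

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            filter_reference_by_type([], AssemblageClass.Type1)


class TestScalingFactor:
    def test_ratio_by_definition(self):
        # constant lists make the percentile trivially the value itself
        result = compute_scaling_factor([0.50] * 10, [0.55] * 10, 95)
        assert result.factor == pytest.approx(1.10, abs=1e-12)

    def test_identity_for_identical_samples(self):
        vals = list(np.linspace(0.3, 0.6, 40))
        assert compute_scaling_factor(vals, vals, 95).factor == pytest.approx(1.0, abs=1e-12)

    def test_alignment_is_exact_after_applying(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(0.42, 0.05, 120).clip(0.1)
        reference = rng.normal(0.52, 0.04, 200).clip(0.1)
        res = compute_scaling_factor(sample, reference, 95)
        scaled = sample * res.factor
        assert np.percentile(scaled, 95) == pytest.approx(
            np.percentile(reference, 95), abs=1e-12)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_scaling_factor([], [0.5], 95)


class TestApplyScaling:
    def _prints(self):
        return [PrintRecord(id="a", mrb=0.40, n_ridges=10, rd=5 * 2**0.5 / 0.40),
                PrintRecord(id="b", mrb=0.50, n_ridges=8)]

    def test_factor_one_is_identity(self):
        prints = self._prints()
        assert [p.mrb for p in apply_scaling(prints, 1.0)] == [0.40, 0.50]

    def test_multiplication_and_rd_recompute(self):
        scaled = apply_scaling(self._prints(), 1.1)
        assert scaled[0].mrb == pytest.approx(0.44)
        assert scaled[0].rd == pytest.approx(5 * 2**0.5 / 0.44)
        assert scaled[1].rd is None
        assert scaled[0].id == "a" and scaled[0].n_ridges == 10

    def test_exact_inversion(self):
        prints = self._prints()
        back = apply_scaling(apply_scaling(prints, 1.37), 1 / 1.37)
        for a, b in zip(prints, back):
            assert b.mrb == pytest.approx(a.mrb, abs=1e-12)

    def test_cv_and_type_invariant_under_scaling(self):
        rng = np.random.default_rng(11)
        prints = [PrintRecord(id=str(i), mrb=float(m), n_ridges=10)
                  for i, m in enumerate(rng.uniform(0.3, 0.6, 80))]
        cv0 = coefficient_of_variation([p.mrb for p in prints])
        scaled = apply_scaling(prints, 1.23)
        cv1 = coefficient_of_variation([p.mrb for p in scaled])
        assert cv1 == pytest.approx(cv0, abs=1e-12)
        assert classify_assemblage(cv1).value is classify_assemblage(cv0).value


class TestAlternateAlignmentSex:
    def test_female_alignment_uses_adult_women_only(self, mixed_reference):
        # contexts where male potting is implausible: align on adult females
        prints = [PrintRecord(id=str(i), mrb=m, n_ridges=10)
                  for i, m in enumerate([0.40, 0.42, 0.44, 0.46])]
        scaled, res = scale_assemblage(prints, mixed_reference,
                                       AssemblageClass.Type1, alignment_sex=1)
        adult_f = [r.mrb for r in mixed_reference if r.sex == 1 and r.age >= 15]
        assert res.reference_percentile_value == pytest.approx(
            np.percentile(adult_f, 95))


class TestPercentileChoiceStability:
    def test_95_vs_97_5_close_when_population_matches_reference(
            self, growth, reference_population):
        # a large simulated assemblage drawn from the same growth curve:
        # the choice between the two customary percentiles barely moves the factor
        asm = generate_assemblage(
            Scenario(n=250, prop_female=0.5, mu_age_f=25, mu_age_m=25,
                     sd_age_f=10, sd_age_m=10, seed=99), growth)
        sample = [p.mrb for p in asm.prints]
        ref = [r.mrb for r in reference_population]
        f95 = compute_scaling_factor(sample, ref, 95).factor
        f975 = compute_scaling_factor(sample, ref, 97.5).factor
        assert abs(f95 - f975) / f95 < 0.05
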