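"""Asymptotic growth curve: closed-form values, fitting, equivariance."""
import math

import numpy as np
import pytest

from ridgemix import GrowthParams, ReferenceRecord, expected_mrb, fit_growth_curve
from ridgemix.growth import default_growth_params


class TestExpectedMrb:
    def test_age_zero_gives_r0(self, growth):
        for sex in (1, 2):
            assert expected_mrb(0.0, sex, growth) == pytest.approx(growth.r0[sex])

    def test_large_age_reaches_asymptote(self, growth):
        for sex in (1, 2):
            assert expected_mrb(1e6, sex, growth) == pytest.approx(
                growth.asym[sex], abs=1e-12)

    def test_independent_arithmetic_value(self):
        # 0.55 + (0.15 - 0.55) * exp(-e^{-2} * 10) computed by hand
        g = GrowthParams(asym={1: 0.55, 2: 0.55}, r0={1: 0.15, 2: 0.15},
                         lrc={1: -2.0, 2: -2.0})
        assert expected_mrb(10.0, 2, g) == pytest.approx(0.44664, abs=1e-4)

    def test_strictly_increasing_and_bounded(self, growth):
        ages = np.linspace(0, 90, 200)
        for sex in (1, 2):
            vals = expected_mrb(ages, sex, growth)
            assert np.all(np.diff(vals) > 0)
            assert np.all(vals >= growth.r0[sex])
            assert np.all(vals <= growth.asym[sex])

    def test_equal_parameters_coincide_across_sexes(self):
        g = GrowthParams(asym={1: 0.5, 2: 0.5}, r0={1: 0.1, 2: 0.1},
                         lrc={1: -1.5, 2: -1.5})
        ages = np.linspace(0, 60, 50)
        assert np.allclose(expected_mrb(ages, 1, g), expected_mrb(ages, 2, g))

    def test_negative_age_rejected(self, growth):
        with pytest.raises(ValueError):
            expected_mrb(-1.0, 1, growth)


def _records_from_curve(g, noise_sd=0.0, n_per_sex=40, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for sex in (1, 2):
        # denser coverage of childhood, where the curve actually bends
        ages = 70.0 * np.linspace(0, 1, n_per_sex) ** 1.7
        for age in ages:
            mrb = expected_mrb(age, sex, g) + (rng.normal(0, noise_sd) if noise_sd else 0.0)
            records.append(ReferenceRecord(age=float(age), sex=sex, mrb=max(mrb, 1e-3)))
    return records


class TestFitGrowthCurve:
    def test_noiseless_self_consistency(self, growth):
        fitted = fit_growth_curve(_records_from_curve(growth))
        for sex in (1, 2):
            assert fitted.asym[sex] == pytest.approx(growth.asym[sex], rel=1e-6)
            assert fitted.r0[sex] == pytest.approx(growth.r0[sex], rel=1e-6)
            assert fitted.lrc[sex] == pytest.approx(growth.lrc[sex], rel=1e-5)
        assert fitted.provenance == "fitted"

    def test_noisy_recovery_within_ten_percent(self, growth):
        records = _records_from_curve(growth, noise_sd=0.03, n_per_sex=150, seed=5)
        fitted = fit_growth_curve(records)
        for sex in (1, 2):
            assert fitted.asym[sex] == pytest.approx(growth.asym[sex], rel=0.10)
            assert fitted.r0[sex] == pytest.approx(growth.r0[sex], rel=0.10)
        assert fitted.sigma == pytest.approx(0.03, rel=0.15)

    def test_degenerate_age_range_rejected(self):
        records = [ReferenceRecord(age=20, sex=s, mrb=0.5)
                   for s in (1, 2) for _ in range(12)]
        with pytest.raises(ValueError):
            fit_growth_curve(records)

    def test_too_few_records_rejected(self):
        records = [ReferenceRecord(age=a, sex=1, mrb=0.4) for a in range(5)]
        with pytest.raises(ValueError):
            fit_growth_curve(records)

    def test_scale_equivariance(self, growth):
        # multiplying reference MRB by k scales asym/r0/sigma by k, lrc unchanged
        k = 1.17
        base = _records_from_curve(growth, noise_sd=0.02, n_per_sex=80, seed=9)
        scaled = [ReferenceRecord(age=r.age, sex=r.sex, mrb=k * r.mrb) for r in base]
        f1 = fit_growth_curve(base)
        f2 = fit_growth_curve(scaled)
        for sex in (1, 2):
            assert f2.asym[sex] == pytest.approx(k * f1.asym[sex], rel=1e-4)
            assert f2.r0[sex] == pytest.approx(k * f1.r0[sex], rel=1e-3)
            assert f2.lrc[sex] == pytest.approx(f1.lrc[sex], abs=1e-3)
        assert f2.sigma == pytest.approx(k * f1.sigma, rel=1e-4)


class TestDefaultGrowthParams:
    def test_fallback_to_package_defaults(self):
        g = default_growth_params(None)
        assert g.provenance == "package default"
        # male plateau above female, both above the shared infant value
        assert g.asym[2] > g.asym[1] > g.r0[1]

    def test_fitted_when_reference_supplied(self, growth):
        g = default_growth_params(_records_from_curve(growth))
        assert g.provenance == "fitted"

    def test_invariant_asym_exceeds_r0(self):
        with pytest.raises(ValueError):
            GrowthParams(asym={1: 0.2, 2: 0.5}, r0={1: 0.3, 2: 0.15})
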