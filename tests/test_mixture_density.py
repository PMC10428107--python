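"""Mixture likelihood against brute-force oracles, and prior behavior."""
import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from ridgemix import DemographyParams, GrowthParams, ModelSpec, log_likelihood
from ridgemix.growth import expected_mrb
from ridgemix.mixture import MixtureDensity, log_posterior


def brute_force_loglik(demography, growth, data, constrain_max=True):
    """Independent oracle: enumerate sexes, integrate age with adaptive quad."""
    def comp(x, sex):
        al, be = demography.alpha[sex], demography.beta[sex]
        return quad(
            lambda a: norm.pdf(x, expected_mrb(a, sex, growth), growth.sigma)
            * gamma_dist.pdf(a, al, scale=1.0 / be),
            0, 100, limit=500)[0]

    w = {1: 1.0 - demography.prob_male, 2: demography.prob_male}
    imax = int(np.argmax(data))
    total = 0.0
    for i, x in enumerate(data):
        if constrain_max and i == imax:
            total += np.log(w[2] * comp(x, 2))
        else:
            total += np.log(w[1] * comp(x, 1) + w[2] * comp(x, 2))
    return total


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("data,pm,muf,mum,sdf,sdm", [
        ([0.45], 0.5, 20.0, 25.0, 5.0, 5.0),
        ([0.42, 0.51], 0.4, 25.0, 18.0, 6.0, 3.0),
        ([0.38, 0.47, 0.55], 0.6, 12.0, 30.0, 4.0, 8.0),
    ])
    def test_quadrature_matches_adaptive_integration(self, growth, data, pm,
                                                     muf, mum, sdf, sdm):
        demo = DemographyParams(prob_male=pm, mu_age={1: muf, 2: mum},
                                sd_age={1: sdf, 2: sdm})
        expected = brute_force_loglik(demo, growth, data)
        got = log_likelihood(demo, growth, data, ModelSpec(), n_nodes=200)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_unconstrained_variant(self, growth):
        demo = DemographyParams(prob_male=0.3, mu_age={1: 22.0, 2: 16.0},
                                sd_age={1: 7.0, 2: 2.5})
        data = [0.40, 0.52]
        spec = ModelSpec(constrain_max_is_male=False)
        expected = brute_force_loglik(demo, growth, data, constrain_max=False)
        assert log_likelihood(demo, growth, data, spec) == pytest.approx(
            expected, abs=1e-6)


class TestDegenerateEquivalences:
    def test_one_sex_model_equals_collapsed_two_sex(self, growth):
        """All-male two-sex model with duplicated age components equals the
        one-sex two-age model sharing the same parameters."""
        data = [0.44, 0.50, 0.55]
        # one_sex_two_age with groups (mu1, mu2) and weight w
        demo1 = DemographyParams(prob_male=1.0, mu_age={1: 12.0, 2: 30.0},
                                 sd_age={1: 3.0, 2: 6.0}, group_weight=0.4)
        ll1 = log_likelihood(demo1, growth, data,
                             ModelSpec(variant="one_sex_two_age"))
        # brute force for the same two-component male-curve mixture
        def comp(x, mu, sd):
            al, be = mu**2 / sd**2, mu / sd**2
            return quad(
                lambda a: norm.pdf(x, expected_mrb(a, 2, growth), growth.sigma)
                * gamma_dist.pdf(a, al, scale=1.0 / be), 0, 100, limit=500)[0]
        expected = sum(
            np.log(0.4 * comp(x, 12.0, 3.0) + 0.6 * comp(x, 30.0, 6.0))
            for x in data)
        assert ll1 == pytest.approx(expected, abs=1e-6)

    def test_shared_age_variant_with_equal_curves_is_one_component(self):
        """two_sex_one_age with identical growth curves across sexes equals a
        single-component model regardless of the sex ratio."""
        g = GrowthParams(asym={1: 0.5, 2: 0.5}, r0={1: 0.15, 2: 0.15},
                         lrc={1: -2.0, 2: -2.0})
        data = [0.42, 0.47, 0.49]
        spec = ModelSpec(variant="two_sex_one_age", constrain_max_is_male=False)
        demo_a = DemographyParams(prob_male=0.3, mu_age={"shared": 20.0},
                                  sd_age={"shared": 6.0})
        demo_b = DemographyParams(prob_male=0.8, mu_age={"shared": 20.0},
                                  sd_age={"shared": 6.0})
        ll_a = log_likelihood(demo_a, g, data, spec)
        ll_b = log_likelihood(demo_b, g, data, spec)
        assert ll_a == pytest.approx(ll_b, abs=1e-8)

    def test_large_sigma_washes_out_age_information(self, growth):
        """With sigma huge, the likelihood barely depends on the age moments."""
        import dataclasses
        g_wide = GrowthParams(sigma=50.0)
        data = [0.44, 0.52]
        spec = ModelSpec(constrain_max_is_male=False)
        demo1 = DemographyParams(prob_male=0.5, mu_age={1: 10.0, 2: 10.0},
                                 sd_age={1: 2.0, 2: 2.0})
        demo2 = DemographyParams(prob_male=0.5, mu_age={1: 40.0, 2: 40.0},
                                 sd_age={1: 8.0, 2: 8.0})
        ll1 = log_likelihood(demo1, g_wide, data, spec)
        ll2 = log_likelihood(demo2, g_wide, data, spec)
        assert ll1 == pytest.approx(ll2, abs=1e-3)


class TestConstraintHandling:
    def test_constraint_restricts_largest_print_to_male(self, growth):
        """With the constraint on and prob_male -> 0, the constrained print's
        male-only factor drives the likelihood down."""
        data = [0.40, 0.56]
        demo_lo = DemographyParams(prob_male=1e-9, mu_age={1: 20.0, 2: 30.0},
                                   sd_age={1: 5.0, 2: 5.0})
        ll_con = log_likelihood(demo_lo, growth, data, ModelSpec())
        ll_unc = log_likelihood(demo_lo, growth, data,
                                ModelSpec(constrain_max_is_male=False))
        assert ll_con < ll_unc - 5  # log(probMale) penalty bites

    def test_tie_broken_by_input_order(self, growth):
        data = np.array([0.5, 0.5, 0.4])
        den = MixtureDensity(data, ModelSpec(), growth)
        assert den.constrained == 0


class TestLogPosterior:
    def test_adds_finite_prior(self, growth):
        demo = DemographyParams(prob_male=0.5, mu_age={1: 20.0, 2: 20.0},
                                sd_age={1: 5.0, 2: 5.0})
        data = [0.45, 0.5]
        lp = log_posterior(demo, growth, data)
        ll = log_likelihood(demo, growth, data)
        assert np.isfinite(lp) and lp != ll

    def test_moment_matching_invariant(self):
        demo = DemographyParams(prob_male=0.5, mu_age={1: 23.0, 2: 31.0},
                                sd_age={1: 4.0, 2: 9.0})
        for s in (1, 2):
            assert demo.alpha[s] == pytest.approx(demo.mu_age[s]**2 / demo.sd_age[s]**2,
                                                  abs=1e-10)
            assert demo.beta[s] == pytest.approx(demo.mu_age[s] / demo.sd_age[s]**2,
                                                 abs=1e-10)

    def test_invalid_demography_rejected(self):
        with pytest.raises(ValueError):
            DemographyParams(prob_male=1.5, mu_age={1: 20.0, 2: 20.0},
                             sd_age={1: 5.0, 2: 5.0})
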