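# ridgemix

Bayesian inference of the **age and sex composition of ancient potters** from
the fingerprint impressions they left on ceramics.

The width of epidermal ridge–furrow pairs — measured as *mean ridge breadth*
(MRB, mm/ridge) or equivalently *ridge density* (RD = 5√2/MRB, ridges per
25 mm² diagonal) — grows with body size through childhood and plateaus at
sex-specific adult values. A single print is therefore deeply ambiguous: an
adult woman and an adolescent boy produce the same MRB, and ceramic
shrinkage (2–12%) plus between-population body-size differences rescale
every measurement by an unknown factor. `ridgemix` resolves what can be
resolved by pooling an entire assemblage:

1. **Characterize** — the coefficient of variation of MRB coarsely types the
   assemblage (Type 1: single-sex adults, CV < 0.09; Type 2: mixed
   adults/adolescents, CV 0.09–0.11; Type 3: children present, CV > 0.11).
2. **Scale** — assuming some adult men contributed, aligning the
   assemblage's 95th-percentile MRB with a modern reference population's
   absorbs shrinkage and population differences into one multiplicative
   factor.
3. **Infer** — a Bayesian mixture model: print *i* has latent sex
   `sexᵢ ~ Bernoulli(probMale)` and age `ageᵢ ~ Gamma(α_s, β_s)` with
   per-sex moment-matched shape/rate (`α = μ²/σ²`, `β = μ/σ²`); observed
   `MRBᵢ ~ Normal(u(ageᵢ, sexᵢ), σ)` where
   `u(x, s) = Asym_s + (R0_s − Asym_s)·exp(−exp(lrc_s)·x)` is the
   asymptotic growth curve. Multi-chain MCMC (10 chains by default) runs
   until every monitored parameter reaches effective sample size > 3000 and
   a Gelman–Rubin upper confidence bound ≤ 1.01.
4. **Compare** — model variants (shared age distribution across sexes;
   single-sex with two age groups) are weighed by Bayes factors computed
   with a product-space ("supermodel") sampler.
5. **Benchmark** — a 540-cell factorial simulation design scores the model
   against per-print estimators from the earlier literature (affine
   age-on-MRB rules, an RD-threshold sex rule, and random baselines) by
   mean absolute error.

The package is aimed at archaeologists and biological anthropologists
working with measured ridge impressions (it consumes tables of MRB values,
not fingerprint images).

## Worked example

Simulate a workforce of young girls (mean age 9) and adult men (mean age
35), then fit the standard two-sex model:

```python
from ridgemix import (GrowthParams, MCMCConfig, ModelSpec,
                      sample_posterior, summarize_individuals)
from ridgemix.simulate import Scenario, generate_assemblage

growth = GrowthParams()        # packaged stand-in growth curve
scenario = Scenario(n=100, prop_female=0.5, mu_age_f=9, mu_age_m=35,
                    sd_age_f=3, sd_age_m=8, seed=11)
assemblage = generate_assemblage(scenario, growth)

config = MCMCConfig(n_chains=4, ess_target=400, rhat_target=1.05,
                    warmup=3000, initial_draws=6000, max_iterations=24000)
traces = sample_posterior([p.mrb for p in assemblage.prints],
                          ModelSpec(), growth, config, seed=2)
print(summarize_individuals(traces).head(6).round(3))
```

prints (`examples/03_fit_mixture_model.py` runs the full script, including
the population summary):

```
     mrb  p_male  age_mean  age_q2.5  age_q97.5   # truth
0  0.342   0.027    19.650     5.717     49.389   # girl, age 8.1
1  0.322   0.029    19.045     5.162     49.389   # girl, age 9.9
2  0.540   0.994    24.867     8.878     54.273   # man, age 41.1
3  0.352   0.028    19.920     6.297     49.389   # girl, age 8.4
4  0.322   0.029    19.036     5.162     49.389   # girl, age 5.4
5  0.493   0.907    21.925     6.904     50.611   # man, age 26.4
```

The posterior sex ratio (`prob_male` mean 0.47) recovers the simulated
50/50 split and every print's sex is called essentially correctly
(`p_male` 0.03 for the girls, > 0.9 for the men). The per-print age
intervals stay wide: a small print could be a child *or* an adult from a
smaller-bodied population whose growth curve sits lower — exactly the
ambiguity the priors on the growth parameters are designed to admit. That
uncertainty is the honest answer at assemblage level; it narrows only with
a fitted reference population (tighter growth priors).

`examples/` contains one short script per capability (characterize, scale,
fit, compare, benchmark). A thin CLI mirrors the same five stages:
`ridgemix characterize|scale|fit|compare|simulate|benchmark --help`.

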