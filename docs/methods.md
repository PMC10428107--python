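# Methods

## The inference problem

A fingerprint's mean ridge breadth (MRB, mm/ridge) is fixed in pattern
before birth and stretches with hand growth, so it tracks body size: MRB
rises near-linearly through childhood, plateaus at adolescence (earlier in
girls than boys), and stays constant through adulthood at a sex-specific
level. Consequences for inference from a single print: children's ages are
estimable but not their sex; adults' sex is estimable but not their age;
and adult women overlap adolescent boys completely. On top of this,
ceramic shrinkage during drying/firing (~2–12%) and between-population
body-size differences multiply every MRB in an assemblage by an unknown
common factor. `ridgemix` therefore treats the *distribution* of MRB
values in an assemblage — not individual prints — as the unit of evidence.

## Pipeline stages

### Assemblage characterization

Prints with fewer than `min_ridges` (default 6) ridges averaged are
excluded: few-ridge measurements inflate the variance of the per-print
mean. Extreme outliers are removed for the CV computation only, by robust
z-score: |x − median| / (1.4826·MAD) > 3.5 (configurable). The MAD is used
precisely because it resists the outliers being screened; if MAD = 0 with
unequal values the rule falls back to an SD z-score with a warning. The
full (non-outlier-screened) dataset still goes to the mixture model, whose
Gaussian likelihood handles stragglers gracefully.

The coefficient of variation uses the n−1 sample SD (assemblages are
small). Typing: CV < 0.09 → Type 1, 0.09 ≤ CV ≤ 0.11 → Type 2,
CV > 0.11 → Type 3. Boundary values are assigned to the intermediate type
— the classification is explicitly coarse — and CVs within 0.005 of a
bound carry a `near_boundary` flag.

### Scaling

One multiplicative factor aligns the assemblage's upper-percentile MRB
(95th by default; 97.5th gives factors within a few percent on ≥ 200
prints) with the corresponding percentile of a reference population
filtered by assemblage type: Type 1 → adult (≥ 15 y) males only, Type 2 →
both sexes ≥ 15 y, Type 3 → the full reference. The male-alignment default
encodes the assumption that *some* adult men contributed to the
assemblage; it is logged on every run, and an alternate female-alignment
mode exists for contexts where male potting is implausible. Percentiles
use linear interpolation between order statistics (quantile type 7).
Scaling is exactly invertible, and the CV — hence the assemblage type — is
invariant under it.

### Growth curve

Expected MRB at age x for sex s is the asymptotic-regression form

    u(x, s) = Asym_s + (R0_s − Asym_s) · exp(−exp(lrc_s) · x)

(R0 = value at birth, Asym = adult plateau, lrc = log rate constant), with
Gaussian residual SD σ pooled across sexes. `fit_growth_curve` fits this
per sex by nonlinear least squares with a self-start (Asym ← max MRB,
R0 ← min MRB, lrc ← log 0.15) and takes σ as the pooled RMS residual.

The packaged defaults (Asym 0.47/0.55 mm/ridge female/male, shared
R0 0.15, lrc −2, σ 0.04) are **synthetic stand-ins** chosen to be
demographically plausible; no fitted reference values are redistributed
with the package. Every component — simulator, priors, likelihood — uses
whatever `GrowthParams` object is in effect, so parameter-recovery
experiments are internally valid whatever the stand-in values. Fit real
reference data whenever it is available.

### Mixture model

Per print i: sexᵢ ~ Bernoulli(probMale); ageᵢ | sexᵢ ~ Gamma(α_s, β_s)
with α_s = μ_s²/σ_s², β_s = μ_s/σ_s² (so the hyperparameters are the
interpretable mean and SD of age); MRBᵢ | ageᵢ, sexᵢ ~ Normal(u(ageᵢ,
sexᵢ), σ). Variants: `two_sex_one_age` shares one age distribution across
sexes; `one_sex_two_age` is all-male with two age groups ordered by mean
(μ₁ < μ₂ by construction; the iid base prior restricted to the ordered
half-space is renormalized by 2 so Bayes factors are well defined).
Optionally (`constrain_max_is_male`, default on) the print with the
largest MRB is treated as an observed adult man — men occupy the top of
the MRB range, and the scaling step already leaned on that assumption.
Ties are broken by input order.

Priors (all configurable):

| parameter | prior | default | encodes |
|---|---|---|---|
| probMale | Uniform(0, 1) | — | no prior information on sex ratio |
| μ_age per component | Gamma(mean 20, sd 10) | shape 4, rate 0.2 | most likely ≈ 20 y; 5–45 plausible |
| σ_age per component | Half-Normal(15) | — | small values favored; up to ≈ 35 plausible |
| Asym_s, R0_s | Normal(center, 10% of center) | growth curve in effect | deliberately loose curve priors |
| lrc_s | Normal(center, 0.5) | — | deliberately loose |
| σ | Half-Normal(2 × default σ) | — | residual scale estimated, weakly informed |

### Likelihood computation

The sex indicator is marginalized analytically and the age integral is
evaluated with Gauss–Legendre quadrature, **per component on its own range
[μ − 10σ_age, μ + 10σ_age] ∩ [0, 100]** (64 nodes by default). The
adaptive range matters: a fixed global grid under-resolves age
distributions narrower than its node spacing (~1.2 y at 128 nodes), and
the resulting aliasing manufactures spurious high-likelihood spikes at
small σ_age that trap MCMC chains. A hard floor σ_age ≥ 0.5 y remains as
a guard (sub-half-year workforce age spreads are not meaningful). Ages are
truncated to [0, 100]; component age SDs and means below 0.5 y are
off-support. The kernel is numba-compiled with a pure-numpy reference
implementation kept alongside and cross-checked in the tests; both match a
brute-force oracle (sex enumeration + adaptive quadrature) to 10⁻⁶ on
small datasets.

Per-print age/sex posteriors come from the mixture responsibilities: for
each retained draw, the normalized joint mass over (component, age-node)
per print; averaging these over draws (≤ 300, evenly thinned) gives
P(male)ᵢ, the posterior age density, its mean and central 95% interval.
Population summaries derived from responsibilities (per-sex mean ages,
age-class fractions) are ratios of posterior expectations, which at these
sample sizes track posterior means of the ratios closely.

### Sampler

Each of the (default 10) chains is a 4-level parallel-tempered ladder of
adaptive random-walk Metropolis samplers (inverse temperatures 1 / 0.55 /
0.3 / 0.15 applied to the likelihood only). The posterior is multimodal —
mirror-image component labellings and genuinely competing age/sex
assignments (e.g. "young women + old men" vs "all men of two ages") — and
the hot levels ferry states between basins through adjacent-level swap
proposals each sweep. A deterministic label-swap involution (exchange the
two components' demography, probMale → 1 − probMale) is mixed in during
sampling. Each level adapts its own proposal covariance (scaled empirical
covariance, step size tuned to 23% acceptance) during warmup — restarted a
third of the way in to shed the transient — and freezes afterwards, so the
sampling phase is a fixed kernel. Only cold-level draws are recorded.

Stopping rule: starting chains from independent prior draws, sample in
doubling blocks; after each block require, for every monitored parameter,
effective sample size > `ess_target` (default 3000; arviz's
autocorrelation-based estimator summed across chains) **and** a split-chain
Gelman–Rubin upper 97.5% confidence bound ≤ `rhat_target` (default 1.01;
classical between/within decomposition with the degrees-of-freedom
correction and F-quantile upper bound). Hitting `max_iterations` instead
returns traces flagged `converged=False` with a loud warning. Same seed →
bit-identical traces.

### Model comparison

The product-space (Carlin–Chib) supermodel carries a categorical model
index; posterior model probabilities are its visit frequencies, and Bayes
factors are prior-adjusted posterior odds (a never-visited model is
floored at one visit, reporting a resolvable bound rather than infinity).
The growth curve and σ mean the same thing under every variant and share
one block across the product space; only each variant's demography block
(3–5 dimensions) gets a linking pseudo-prior — a moment-matched normal fit
to a preliminary single-model run, label-mirror draws folded onto the
majority mode first. Keeping pseudo-priors low-dimensional is what keeps
index switching healthy; the sampler raises an error if the index never
switches. Model priors default to uniform. All densities enter fully
normalized (priors included), which the cross-model index update requires.

A caveat established empirically during development: on data with two
well-separated age modes in an all-male population, the standard two-sex
model attains the *same* maximized likelihood as the one-sex/two-age
variant — the female component, with its own flexible growth curve, can
imitate a younger male age group. The Bayes factor between them is then
governed by prior concentration rather than fit, and under this package's
weakly informative defaults it can favor the two-sex model. Model
probabilities for near-equivalent variants should be read as sensitive to
the hyperprior constants.

### Simulation benchmark

`factorial_design` crosses sample size (50/100/200), proportion female
(10/30/50/70/90%), per-sex mean age (15/20/30 y) and per-sex age SD
(2/8 y): 540 scenarios, each with a deterministic seed derived from the
base seed and grid index via splitmix64 mixing (child seeds < 2³¹). The
generator draws sex, then gamma ages, then MRB = u(age, sex) + N(0, σ)
truncated positive, then applies multiplicative shrinkage (default 0;
truth recorded pre-shrinkage). Same scenario + seed → identical data.

Comparators: four affine age-on-MRB rules (PM1, KAmod, LC, LCmod) whose
published coefficients are not redistributable here — the packaged
defaults are stand-ins refit from the growth curve over child/adolescent
age windows (2–20, 2–20 male-curve, 3–15, 2–25 y respectively), where MRB
growth is near-linear; pass real coefficients through the config to
reproduce a specific published rule. KAmod2 assigns sex by ridge density
threshold (male iff rounded RD < 14.9 ridges/25 mm²), with the fractional
RD deliberately rounded *up* for true females and *down* for true males —
a handicap in the rule's favor, using truth it would not have in practice,
reproduced as the benchmark defines it. Baselines: `random` (fair-coin
sex, age ~ Uniform(5, 60)) and `random2` (fair-coin sex, age ~ N(18, 5)
truncated positive).

How well the threshold rule fares depends on where the printed threshold
(14.9 ridges/25 mm², equivalently MRB 0.4745) lands relative to the adult
plateaus of the growth curve in effect: with the packaged stand-ins
(plateaus 0.47/0.55, about two residual SDs apart) it discriminates adult
sexes rather well and only collapses on child-heavy assemblages (children
are uniformly called female). Orderings involving KAmod2 therefore shift
with the growth parameters and should be re-examined against a fitted
reference curve.

Metrics per scenario: total mean age, proportion female, per-sex mean
ages, and per-sex child/adolescent/adult fractions for sex-capable models
(the Bayesian model, KAmod2, the random baselines); mean age and overall
class fractions irrespective of sex for the age-only affine rules.
Age-class bounds default to (12, 20) years — no canonical cutoffs exist in
this literature; the choice is consistent with female growth plateauing at
13–14, male at 15–16, and 15 y marking adults in reference filtering — and
are configurable. Errors are |estimate − truth| against the *realized*
(sampled) truth of each assemblage; proportions on [0, 1], ages in years.
Scenario failures are logged and excluded with a count. Bayesian estimates
inside the benchmark use throttled MCMC settings (4 chains, ESS target
300, R̂ target 1.05) — benchmark conclusions are about error orderings,
not about fully converged single-dataset posteriors.

## What the synthetic generator does and does not emulate

It reproduces the modelled data-generating process exactly: gamma ages,
sex-specific asymptotic growth, homoscedastic Gaussian residuals, scalar
shrinkage. Real assemblages additionally contain interdigital and
intermanual variation within a potter, multiple prints per individual,
age- and sex-dependent participation biases, and measurement error
correlated with print quality — none of which are modelled. Passing
recovery tests on synthetic data therefore demonstrates the *inferential
machinery* works when the model is true, not that the model is adequate
for any particular archaeological assemblage.

## Known limitations

- **Adult ages are weakly identified.** The growth curve is flat past
  adolescence, so an adult component's mean age is informed mostly by its
  prior; posterior means of per-sex mean age shrink toward ~20–25 y, and
  recovery errors of several years for adult-heavy scenarios are inherent,
  not a sampler defect. The per-print intervals honestly reflect this.
- **Adult women vs adolescent boys** remain confusable by construction;
  in scenarios with young men and adult women the sex ratio posterior can
  sit near 0.5 with large uncertainty (and its mean can be badly off).
- The growth-curve defaults are stand-ins; absolute results on real data
  require fitting a real reference population.
- One print = one potter is assumed throughout; hierarchical
  multiple-prints-per-artifact modelling is out of scope.
- Problem sizes in the test suite (8 recovery scenarios at n = 200, a
  12-scenario benchmark subset, throttled MCMC targets for repeated fits)
  were chosen to keep the full suite runnable on a single CPU; the
  package-level defaults implement the full stopping rule.
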