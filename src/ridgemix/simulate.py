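"""Synthetic assemblage generator and the 540-scenario factorial design.

Simulated potters have per-sex gamma-distributed ages (moment-matched
shape/rate), MRB values on the asymptotic growth curve plus Gaussian
residual noise, and optionally a multiplicative ceramic-shrinkage reduction
(2-12% in practice; 0 by default).  Regenerating a scenario with the same
seed reproduces the assemblage bit for bit.

The factorial design crosses sample size (50/100/200), proportion of
females (10/30/50/70/90%), per-sex mean age (15/20/30 years) and per-sex
age SD (2/8 years) independently: 3*5*3*3*2*2 = 540 scenarios.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np

from .datatypes import FEMALE, MALE, PrintRecord
from .growth import GrowthParams, expected_mrb

SAMPLE_SIZES = (50, 100, 200)
PROP_FEMALE_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)
MEAN_AGE_LEVELS = (15.0, 20.0, 30.0)
SD_AGE_LEVELS = (2.0, 8.0)


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation design, with its deterministic seed."""

    n: int
    prop_female: float
    mu_age_f: float
    mu_age_m: float
    sd_age_f: float
    sd_age_m: float
    shrinkage: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must lie in [0, 1]")
        if not 0.0 <= self.shrinkage < 1.0:
            raise ValueError("shrinkage must lie in [0, 1)")
        for v in (self.mu_age_f, self.mu_age_m, self.sd_age_f, self.sd_age_m):
            if v <= 0:
                raise ValueError("age means and SDs must be positive")


@dataclass
class SyntheticAssemblage:
    prints: list
    true_ages: np.ndarray
    true_sexes: np.ndarray            # {1, 2}
    scenario: Scenario

    @property
    def true_prop_female(self) -> float:
        return float(np.mean(self.true_sexes == FEMALE))

    def true_mean_age(self, sex: Optional[int] = None) -> float:
        if sex is None:
            return float(self.true_ages.mean())
        mask = self.true_sexes == sex
        return float(self.true_ages[mask].mean()) if mask.any() else float("nan")


def _splitmix64(x: int) -> int:
    """Deterministic integer mixing (splitmix64 finalizer)."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def derive_seed(base_seed: int, index: int) -> int:
    """Child seed for scenario ``index``: mixed, kept below 2^31."""
    return _splitmix64(_splitmix64(base_seed) ^ (index + 1)) % (2**31 - 1)


def generate_assemblage(scenario: Scenario,
                        growth: GrowthParams | None = None) -> SyntheticAssemblage:
    """Draw one synthetic assemblage under the scenario's demography.

    Sex ~ Bernoulli (male with probability ``1 - prop_female``); age per sex
    gamma with the scenario's moments; MRB = growth curve + Normal(0, sigma)
    truncated positive, then multiplied by ``1 - shrinkage``.  Truth (ages,
    sexes) is recorded before shrinkage is applied.
    """
    g = growth or GrowthParams()
    rng = np.random.default_rng(scenario.seed)
    male = rng.random(scenario.n) >= scenario.prop_female
    sexes = np.where(male, MALE, FEMALE)
    ages = np.empty(scenario.n)
    for sex, mu, sd in ((FEMALE, scenario.mu_age_f, scenario.sd_age_f),
                        (MALE, scenario.mu_age_m, scenario.sd_age_m)):
        mask = sexes == sex
        shape = mu**2 / sd**2
        scale = sd**2 / mu
        ages[mask] = rng.gamma(shape, scale, size=int(mask.sum()))
    mrbs = np.empty(scenario.n)
    for i in range(scenario.n):
        mu_i = expected_mrb(ages[i], int(sexes[i]), g)
        val = mu_i + g.sigma * rng.standard_normal()
        while val <= 0:  # truncate the residual to keep MRB positive
            val = mu_i + g.sigma * rng.standard_normal()
        mrbs[i] = val
    mrbs *= 1.0 - scenario.shrinkage
    prints = [
        PrintRecord(id=f"sim{scenario.seed}_{i}", mrb=float(mrbs[i]), n_ridges=10)
        for i in range(scenario.n)
    ]
    return SyntheticAssemblage(prints=prints, true_ages=ages, true_sexes=sexes,
                               scenario=scenario)


def factorial_design(base_seed: int = 0, shrinkage: float = 0.0) -> list[Scenario]:
    """The full 540-scenario factorial design with deterministic child seeds."""
    scenarios = []
    grid = product(SAMPLE_SIZES, PROP_FEMALE_LEVELS, MEAN_AGE_LEVELS,
                   MEAN_AGE_LEVELS, SD_AGE_LEVELS, SD_AGE_LEVELS)
    for index, (n, pf, mu_f, mu_m, sd_f, sd_m) in enumerate(grid):
        scenarios.append(Scenario(
            n=n, prop_female=pf, mu_age_f=mu_f, mu_age_m=mu_m,
            sd_age_f=sd_f, sd_age_m=sd_m, shrinkage=shrinkage,
            seed=derive_seed(base_seed, index),
        ))
    return scenarios


def design_subset(design: Sequence[Scenario], size: int, seed: int = 0) -> list[Scenario]:
    """Deterministic subsample of the design (without replacement)."""
    rng = np.random.default_rng(derive_seed(seed, 999_983))
    idx = rng.choice(len(design), size=min(size, len(design)), replace=False)
    return [design[i] for i in sorted(idx)]
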