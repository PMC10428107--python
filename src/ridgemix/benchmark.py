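"""Mean-absolute-error evaluation harness comparing demographic estimators.

For each scenario of the simulation design, each model produces population
estimates — total mean age, the proportion of females, per-sex mean ages and
per-sex child/adolescent/adult fractions for sex-capable models; mean age
and overall age-class fractions irrespective of sex for age-only models —
and the harness records the absolute difference from the values realized in
the simulated assemblage.  Aggregating over scenarios gives the model-by-
metric mean-absolute-error table.

Age-class bounds default to (12, 20) years (child < 12 <= adolescent < 20
<= adult); the literature defines no canonical cutoffs, so the bounds are
configurable and should be stated with any result.  Proportions are on the
[0, 1] scale, ages in years.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comparators import (LINEAR_MODELS, predict_age_linear, predict_kamod2,
                          predict_random, refit_standin_coefficients)
from .config import PipelineConfig
from .datatypes import FEMALE, MALE
from .growth import GrowthParams
from .mixture import ModelSpec, individual_posteriors, sample_posterior
from .simulate import Scenario, SyntheticAssemblage, generate_assemblage

logger = logging.getLogger(__name__)

SEX_CAPABLE_MODELS = ("bayes", "KAmod2", "random", "random2")
AGE_ONLY_MODELS = LINEAR_MODELS
ALL_MODELS = ("bayes",) + AGE_ONLY_MODELS + ("KAmod2", "random", "random2")

SEX_METRICS = (
    "total_mean_age", "pct_female", "mean_age_f", "mean_age_m",
    "pct_child_f", "pct_adol_f", "pct_adult_f",
    "pct_child_m", "pct_adol_m", "pct_adult_m",
)
AGE_ONLY_METRICS = ("total_mean_age", "pct_child", "pct_adol", "pct_adult")


@dataclass(frozen=True)
class EvaluationRow:
    model_id: str
    metric_id: str
    abs_error: float
    scenario_seed: int

    def __post_init__(self):
        if self.abs_error < 0:
            raise ValueError("abs_error must be >= 0")


@dataclass
class PopulationEstimate:
    """Population-level demographic summary of one assemblage or estimate."""

    mean_age: float
    class_fracs: tuple                      # overall (child, adol, adult)
    pct_female: Optional[float] = None
    mean_age_f: Optional[float] = None
    mean_age_m: Optional[float] = None
    class_fracs_f: Optional[tuple] = None
    class_fracs_m: Optional[tuple] = None

    @property
    def sex_capable(self) -> bool:
        return self.pct_female is not None


def age_class_fractions(ages: Sequence[float],
                        bounds: tuple[float, float] = (12.0, 20.0)) -> tuple:
    """(child, adolescent, adult) fractions: [0, b1), [b1, b2), [b2, inf)."""
    b1, b2 = bounds
    if not b1 < b2:
        raise ValueError("age class bounds must be increasing")
    a = np.asarray(list(ages), dtype=float)
    if a.size == 0:
        raise ValueError("cannot compute class fractions of an empty age list")
    child = float(np.mean(a < b1))
    adol = float(np.mean((a >= b1) & (a < b2)))
    return (child, adol, 1.0 - child - adol)


def population_from_predictions(ages, sexes=None,
                                bounds=(12.0, 20.0)) -> PopulationEstimate:
    """Summarize per-print point predictions into a population estimate."""
    ages = np.asarray(ages, dtype=float)
    est = PopulationEstimate(mean_age=float(ages.mean()),
                             class_fracs=age_class_fractions(ages, bounds))
    if sexes is not None:
        sexes = np.asarray(sexes)
        est.pct_female = float(np.mean(sexes == FEMALE))
        for sex, mean_attr, frac_attr in ((FEMALE, "mean_age_f", "class_fracs_f"),
                                          (MALE, "mean_age_m", "class_fracs_m")):
            mask = sexes == sex
            if mask.any():
                setattr(est, mean_attr, float(ages[mask].mean()))
                setattr(est, frac_attr, age_class_fractions(ages[mask], bounds))
    return est


def population_truth(assemblage: SyntheticAssemblage,
                     bounds=(12.0, 20.0)) -> PopulationEstimate:
    """The realized (sampled) demographic truth of a synthetic assemblage."""
    return population_from_predictions(assemblage.true_ages,
                                       assemblage.true_sexes, bounds)


def population_from_posterior(post: dict, variant: str = "two_sex_two_age",
                              bounds=(12.0, 20.0)) -> PopulationEstimate:
    """Population estimate from averaged per-print mixture responsibilities.

    ``post`` is the dict from :func:`ridgemix.mixture.individual_posteriors`.
    Ratio quantities (per-sex means, class fractions) are ratios of posterior
    expectations, which for these sample sizes track the posterior means of
    the ratios closely.
    """
    joint = post["joint"]                      # (n, 2, J)
    grid = post["age_grid"]
    b1, b2 = bounds
    masks = (grid < b1, (grid >= b1) & (grid < b2), grid >= b2)
    n = joint.shape[0]
    age_mass = joint.sum(axis=1)               # (n, J)
    mean_age = float((age_mass @ grid).mean())
    overall = tuple(float(age_mass[:, m].sum() / n) for m in masks)
    est = PopulationEstimate(mean_age=mean_age, class_fracs=overall)
    if variant == "one_sex_two_age":
        # both components male
        est.pct_female = 0.0
        est.mean_age_m = mean_age
        est.class_fracs_m = overall
        return est
    p_male = joint[:, 1, :].sum(axis=1)        # (n,)
    est.pct_female = float(np.mean(1.0 - p_male))
    for c, mean_attr, frac_attr in ((0, "mean_age_f", "class_fracs_f"),
                                    (1, "mean_age_m", "class_fracs_m")):
        mass = joint[:, c, :]                  # (n, J)
        weight = mass.sum()
        if weight > 1e-12:
            setattr(est, mean_attr, float((mass @ grid).sum() / weight))
            setattr(est, frac_attr,
                    tuple(float(mass[:, m].sum() / weight) for m in masks))
    return est


def evaluate_model(estimate: PopulationEstimate, truth: PopulationEstimate,
                   model_id: str = "", scenario_seed: int = 0,
                   irrespective_of_sex: bool = False) -> list[EvaluationRow]:
    """Absolute errors |estimate - truth| for every applicable metric.

    Sex-specific metrics are emitted only when the estimate carries sex
    information and ``irrespective_of_sex`` is off; metrics whose truth is
    undefined (e.g. no women sampled in the scenario) are skipped.
    """
    rows = []

    def emit(metric, est_val, true_val):
        if est_val is None or true_val is None:
            return
        if isinstance(true_val, float) and np.isnan(true_val):
            return
        rows.append(EvaluationRow(model_id=model_id, metric_id=metric,
                                  abs_error=abs(est_val - true_val),
                                  scenario_seed=scenario_seed))

    emit("total_mean_age", estimate.mean_age, truth.mean_age)
    if estimate.sex_capable and not irrespective_of_sex:
        emit("pct_female", estimate.pct_female, truth.pct_female)
        emit("mean_age_f", estimate.mean_age_f, truth.mean_age_f)
        emit("mean_age_m", estimate.mean_age_m, truth.mean_age_m)
        for suffix, est_fr, true_fr in (("f", estimate.class_fracs_f, truth.class_fracs_f),
                                        ("m", estimate.class_fracs_m, truth.class_fracs_m)):
            if est_fr is None or true_fr is None:
                continue
            for k, cls in enumerate(("child", "adol", "adult")):
                emit(f"pct_{cls}_{suffix}", est_fr[k], true_fr[k])
    else:
        for k, cls in enumerate(("child", "adol", "adult")):
            emit(f"pct_{cls}", estimate.class_fracs[k], truth.class_fracs[k])
    return rows


def _benchmark_mcmc(cfg: PipelineConfig):
    """Throttled MCMC settings for the many fits inside the benchmark loop."""
    return dataclasses.replace(
        cfg.mcmc, n_chains=4, ess_target=300.0, rhat_target=1.05,
        warmup=2500, initial_draws=4000, max_iterations=16000,
    )


def _fit_bayes_estimate(mrbs, growth, cfg, seed, bounds, bayes_mcmc=None):
    traces = sample_posterior(mrbs, ModelSpec(), growth,
                              config=bayes_mcmc or _benchmark_mcmc(cfg),
                              seed=seed)
    post = individual_posteriors(traces)
    return population_from_posterior(post, traces.spec.variant, bounds)


def run_benchmark(
    models: Sequence[str],
    design: Sequence[Scenario],
    growth: GrowthParams | None = None,
    config: PipelineConfig | None = None,
    bayes_mcmc=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate, estimate and score every scenario-model pair.

    Returns ``(per_row, aggregate)``: the long table of absolute errors and
    the model-by-metric mean-absolute-error pivot.  Scenario failures are
    logged and excluded with a count, never silently dropped.
    """
    if not models or not design:
        raise ValueError("models and design must be nonempty")
    cfg = config or PipelineConfig()
    g = growth or cfg.growth_defaults
    bounds = cfg.age_class_bounds
    coeffs = cfg.comparator_coefficients or refit_standin_coefficients(g)
    rows: list[EvaluationRow] = []
    n_failures = 0
    for scenario in design:
        try:
            asm = generate_assemblage(scenario, g)
            mrbs = np.array([p.mrb for p in asm.prints])
            truth = population_truth(asm, bounds)
            for model in models:
                if model == "bayes":
                    est = _fit_bayes_estimate(mrbs, g, cfg, scenario.seed, bounds,
                                              bayes_mcmc)
                elif model in LINEAR_MODELS:
                    ages = predict_age_linear(mrbs, model, coeffs)
                    est = population_from_predictions(ages, None, bounds)
                elif model == "KAmod2":
                    ages, sexes = predict_kamod2(mrbs, asm.true_sexes,
                                                 threshold=cfg.kamod2_threshold,
                                                 coefficients=coeffs)
                    est = population_from_predictions(ages, sexes, bounds)
                elif model in ("random", "random2"):
                    ages, sexes = predict_random(len(mrbs), model,
                                                 seed=scenario.seed + 17)
                    est = population_from_predictions(ages, sexes, bounds)
                else:
                    raise ValueError(f"unknown model {model!r}")
                rows.extend(evaluate_model(est, truth, model, scenario.seed))
        except Exception:
            n_failures += 1
            logger.exception("run_benchmark: scenario seed=%d failed; excluded",
                             scenario.seed)
    if n_failures:
        logger.warning("run_benchmark: %d of %d scenarios failed and were excluded",
                       n_failures, len(design))
    per_row = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    aggregate = (per_row.pivot_table(index="model_id", columns="metric_id",
                                     values="abs_error", aggfunc="mean")
                 if not per_row.empty else pd.DataFrame())
    return per_row, aggregate
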