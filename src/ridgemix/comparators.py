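"""Comparator estimators from the prior literature, used by the benchmark.

Four affine age-on-MRB rules (PM1, KAmod, LC, LCmod), the threshold-based
KAmod2 age-and-sex rule, and two random baselines.  The published
coefficients of the affine rules live in their source papers and are not
redistributable from here; the packaged defaults are synthetic stand-ins
refit from the package growth curve over child/adolescent ages (where MRB
growth is near-linear), preserving the structure of each rule.  Pass your
own coefficients via the config to reproduce a specific published rule.
"""
from __future__ import annotations

import numpy as np

from .datatypes import FEMALE, MALE
from .growth import GrowthParams, expected_mrb
from .ridge_metrics import mrb_to_rd

LINEAR_MODELS = ("PM1", "KAmod", "LC", "LCmod")

#: Fitting window (ages, sex-pooling) used for each stand-in refit; the four
#: rules differ in provenance, so the stand-ins are differentiated by window.
_STANDIN_WINDOWS = {
    "PM1": (2.0, 20.0, None),      # pooled sexes
    "KAmod": (2.0, 20.0, MALE),
    "LC": (3.0, 15.0, None),
    "LCmod": (2.0, 25.0, None),
}


def refit_standin_coefficients(growth: GrowthParams | None = None) -> dict:
    """Affine ``age = intercept + slope * MRB`` stand-ins from the growth curve.

    Least-squares fit of age on noiseless expected MRB over each rule's
    age window (dense grid).  Synthetic stand-ins, not the published values.
    """
    g = growth or GrowthParams()
    coeffs = {}
    for name, (lo, hi, sex) in _STANDIN_WINDOWS.items():
        ages = np.linspace(lo, hi, 200)
        if sex is None:
            mrbs = 0.5 * (expected_mrb(ages, FEMALE, g) + expected_mrb(ages, MALE, g))
        else:
            mrbs = expected_mrb(ages, sex, g)
        slope, intercept = np.polyfit(mrbs, ages, 1)
        coeffs[name] = {"intercept": float(intercept), "slope": float(slope)}
    return coeffs


def predict_age_linear(mrbs, model_id: str, coefficients: dict) -> np.ndarray:
    """Per-print affine age prediction, clamped to [0, 100] years."""
    if model_id not in coefficients:
        raise KeyError(
            f"no coefficients for {model_id!r}; add them under "
            f"comparator_coefficients in the config (or use the refit stand-ins)"
        )
    c = coefficients[model_id]
    mrbs = np.asarray(mrbs, dtype=float)
    return np.clip(c["intercept"] + c["slope"] * mrbs, 0.0, 100.0)


def predict_kamod2(mrbs, true_sexes, threshold: float = 14.9,
                   coefficients: dict | None = None,
                   growth: GrowthParams | None = None):
    """Threshold sex rule on ridge density plus the KAmod age rule.

    RD is computed as 5*sqrt(2)/MRB; the fractional RD is rounded *up* for
    true females and *down* for true males — a deliberate handicap in the
    rule's favor, using truth it would not have in practice — and a print is
    called male when the rounded RD falls below the threshold (default 14.9
    ridges/25 mm^2, a logistic-regression optimum; the older literature used
    13).  Returns ``(ages, sexes)`` with sexes in {1, 2}.
    """
    mrbs = np.asarray(mrbs, dtype=float)
    true_sexes = np.asarray(true_sexes)
    if mrbs.shape != true_sexes.shape:
        raise ValueError("mrbs and true_sexes must have the same length")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rd = mrb_to_rd(mrbs)
    rounded = np.where(true_sexes == FEMALE, np.ceil(rd), np.floor(rd))
    sexes = np.where(rounded < threshold, MALE, FEMALE)
    if coefficients is None:
        coefficients = refit_standin_coefficients(growth)
    ages = predict_age_linear(mrbs, "KAmod", coefficients)
    return ages, sexes


def predict_random(n: int, variant: str = "random", seed: int = 0):
    """Random-guessing baselines.

    ``random``: sex fair coin, age Uniform(5, 60).  ``random2`` (educated
    guess): sex fair coin, age Normal(18, 5) truncated positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sexes = np.where(rng.random(n) < 0.5, FEMALE, MALE)
    if variant == "random":
        ages = rng.uniform(5.0, 60.0, size=n)
    elif variant == "random2":
        ages = rng.normal(18.0, 5.0, size=n)
        while np.any(ages <= 0):
            bad = ages <= 0
            ages[bad] = rng.normal(18.0, 5.0, size=int(bad.sum()))
    else:
        raise ValueError(f"unknown random variant {variant!r}")
    return ages, sexes
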