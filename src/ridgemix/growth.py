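"""Asymptotic MRB-versus-age growth curve, shared by the simulator, the
priors and the mixture likelihood.

The expected mean ridge breadth of a person of age ``x`` and sex ``s`` is the
standard asymptotic-regression form

    mu(x, s) = Asym_s + (R0_s - Asym_s) * exp(-exp(lrc_s) * x)

where ``R0`` is the value at birth, ``Asym`` the adult plateau and ``lrc``
the log of the rate constant.  Observed MRB scatters around the curve with
Gaussian residual SD ``sigma``.

The packaged default parameters are synthetic stand-ins, chosen to be
demographically plausible (adult male plateau above adult female, shared
infant value); fit your own reference data with :func:`fit_growth_curve`
whenever one is available.  Every component of this package — simulator,
priors, likelihood — uses whatever :class:`GrowthParams` is in effect, so
analyses are internally consistent regardless of the stand-in values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import FEMALE, MALE, ReferenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthParams:
    """Per-sex asymptotic growth parameters plus residual SD.

    Each per-sex field is a mapping ``{1: female value, 2: male value}``;
    units are mm/ridge except ``lrc`` (log rate constant, 1/year on the
    natural scale) .
    """

    asym: dict = field(default_factory=lambda: {FEMALE: 0.47, MALE: 0.55})
    r0: dict = field(default_factory=lambda: {FEMALE: 0.15, MALE: 0.15})
    lrc: dict = field(default_factory=lambda: {FEMALE: -2.0, MALE: -2.0})
    sigma: float = 0.04
    provenance: str = "package default"

    def __post_init__(self):
        for s in (FEMALE, MALE):
            if not self.asym[s] > self.r0[s]:
                raise ValueError(
                    f"asym must exceed r0 for sex {s} (ridges widen with growth): "
                    f"asym={self.asym[s]}, r0={self.r0[s]}"
                )
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    def as_arrays(self):
        """(asym, r0, lrc) each as float arrays indexed [female, male]."""
        return (
            np.array([self.asym[FEMALE], self.asym[MALE]]),
            np.array([self.r0[FEMALE], self.r0[MALE]]),
            np.array([self.lrc[FEMALE], self.lrc[MALE]]),
        )


def asymptotic_curve(age, asym, r0, lrc):
    """Vectorized asymptotic regression y = Asym + (R0 - Asym) e^{-e^{lrc} age}."""
    age = np.asarray(age, dtype=float)
    return asym + (r0 - asym) * np.exp(-np.exp(lrc) * age)


def expected_mrb(age, sex: int, params: GrowthParams):
    """Expected MRB (mm/ridge) at ``age`` years for ``sex`` (1=f, 2=m)."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0):
        raise ValueError("age must be >= 0")
    out = asymptotic_curve(age_arr, params.asym[sex], params.r0[sex], params.lrc[sex])
    return float(out) if out.ndim == 0 else out


def _fit_one_sex(ages: np.ndarray, mrbs: np.ndarray):
    if np.ptp(ages) == 0:
        raise ValueError("degenerate age range: all reference ages identical")
    # self-start: plateau from the max, birth value from the min, moderate rate
    p0 = (float(mrbs.max()), float(mrbs.min()), np.log(0.15))
    try:
        popt, _ = curve_fit(asymptotic_curve, ages, mrbs, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise ValueError(
            f"growth-curve fit failed to converge (self-start {p0}): {exc}"
        ) from exc
    return popt


def fit_growth_curve(records: Sequence[ReferenceRecord]) -> GrowthParams:
    """Nonlinear least-squares fit of the asymptotic curve, separately per sex.

    Requires at least 10 records per sex spanning child and adult ages.
    ``sigma`` is the pooled root-mean-square residual across both sexes.
    """
    by_sex = {s: [(r.age, r.mrb) for r in records if r.sex == s] for s in (FEMALE, MALE)}
    for s, rows in by_sex.items():
        if len(rows) < 10:
            raise ValueError(f"need >= 10 reference records for sex {s}, got {len(rows)}")
    asym, r0, lrc = {}, {}, {}
    sq_resid, n_tot = 0.0, 0
    for s, rows in by_sex.items():
        ages = np.array([a for a, _ in rows])
        mrbs = np.array([m for _, m in rows])
        popt = _fit_one_sex(ages, mrbs)
        asym[s], r0[s], lrc[s] = map(float, popt)
        resid = mrbs - asymptotic_curve(ages, *popt)
        sq_resid += float(resid @ resid)
        n_tot += len(rows)
    sigma = float(np.sqrt(sq_resid / n_tot))
    if sigma == 0:
        sigma = 1e-9  # noiseless synthetic input; keep the type invariant
    logger.info("fit_growth_curve: fitted %d records, pooled sigma=%.5f", n_tot, sigma)
    return GrowthParams(asym=asym, r0=r0, lrc=lrc, sigma=sigma, provenance="fitted")


def default_growth_params(reference: Sequence[ReferenceRecord] | None = None,
                          defaults: GrowthParams | None = None) -> GrowthParams:
    """Growth parameters in effect: fitted when a reference is supplied,
    otherwise the configured (or packaged) defaults."""
    if reference:
        return fit_growth_curve(reference)
    return defaults if defaults is not None else GrowthParams()
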