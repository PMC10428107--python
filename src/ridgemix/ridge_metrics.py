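"""Ridge-breadth metrics: MRB/RD conversion, quality filtering, coefficient of
variation with robust outlier removal, and coarse assemblage typing.

An assemblage's coefficient of variation (CV) of mean ridge breadth gives a
rough demographic read: single-sex adult groups are tight (low CV), groups
spanning childhood and adulthood are wide (high CV).  The typing is
deliberately coarse; values near a boundary are flagged.
"""
from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import PrintRecord

logger = logging.getLogger(__name__)

_SQRT2_TIMES_5 = 5.0 * math.sqrt(2.0)

#: Robust z-score consistency constant: 1/Phi^{-1}(3/4), makes MAD estimate sigma
#: for normal data.
MAD_SCALE = 1.4826


class AssemblageClass(enum.Enum):
    """Coarse demographic class of an assemblage, from its MRB CV.

    Type1: solely adult men or solely adult women (low CV).
    Type2: adult men and women together, or adult women with adolescents
           (intermediate CV).
    Type3: growing children, possibly with adults (high CV).
    """

    Type1 = 1
    Type2 = 2
    Type3 = 3


@dataclass(frozen=True)
class AssemblageType:
    value: AssemblageClass
    cv: float
    n_used: int = 0
    near_boundary: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = " (near boundary)" if self.near_boundary else ""
        return f"{self.value.name} (CV={self.cv:.4f}, n={self.n_used}){flag}"


def mrb_to_rd(mrb):
    """Convert mean ridge breadth (mm/ridge) to ridge density (ridges/25 mm^2).

    RD counts ridges crossing the diagonal of a 5x5 mm square, so
    ``RD = 5*sqrt(2) / MRB``.
    """
    mrb = np.asarray(mrb, dtype=float)
    if np.any(mrb <= 0):
        raise ValueError("mrb must be > 0")
    out = _SQRT2_TIMES_5 / mrb
    return float(out) if out.ndim == 0 else out


def rd_to_mrb(rd):
    """Inverse of :func:`mrb_to_rd`: ``MRB = 5*sqrt(2) / RD``."""
    rd = np.asarray(rd, dtype=float)
    if np.any(rd <= 0):
        raise ValueError("rd must be > 0")
    out = _SQRT2_TIMES_5 / rd
    return float(out) if out.ndim == 0 else out


def filter_prints(prints: Sequence[PrintRecord], min_ridges: int = 6) -> list[PrintRecord]:
    """Drop prints with fewer than ``min_ridges`` ridges averaged.

    CV is inflated when few ridges are averaged per print, so low-coverage
    measurements are excluded before characterization (default minimum 6;
    10 or more is preferable when sample size allows).  Order is preserved
    and surviving records are untouched.
    """
    if min_ridges < 1:
        raise ValueError("min_ridges must be >= 1")
    kept = [p for p in prints if p.n_ridges >= min_ridges]
    removed = len(prints) - len(kept)
    if removed:
        logger.info("filter_prints: removed %d of %d prints with n_ridges < %d",
                    removed, len(prints), min_ridges)
    if not kept:
        logger.warning("filter_prints: no prints survive the min_ridges=%d filter", min_ridges)
    return kept


def remove_extreme_outliers(
    values: Sequence[float], threshold: float = 3.5
) -> list[float]:
    """Remove extreme outliers by robust z-score before computing the CV.

    A value is extreme when ``|x - median| / (1.4826 * MAD) > threshold``.
    If the MAD is zero but values differ, falls back to an SD-based z-score
    with a warning.  The full dataset still goes to the mixture model;
    removal here only stabilizes the CV used for typing.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values for outlier screening")
    if not np.isfinite(threshold):
        return list(map(float, vals))
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        if np.all(vals == vals[0]):
            return list(map(float, vals))
        logger.warning("remove_extreme_outliers: MAD is zero; falling back to SD rule")
        sd = np.std(vals, ddof=1)
        z = np.abs(vals - np.mean(vals)) / sd
    else:
        z = np.abs(vals - med) / (MAD_SCALE * mad)
    keep = z <= threshold
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("remove_extreme_outliers: removed %d of %d values", n_removed, vals.size)
    return list(map(float, vals[keep]))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample CV: standard deviation (n-1 denominator) divided by the mean."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(vals.std(ddof=1) / mean)


def classify_assemblage(
    cv: float,
    bounds: tuple[float, float] = (0.09, 0.11),
    n_used: int = 0,
    near_boundary_margin: float = 0.005,
) -> AssemblageType:
    """Assign the coarse assemblage class from the MRB coefficient of variation.

    ``cv < lower`` is Type1, ``lower <= cv <= upper`` Type2, ``cv > upper``
    Type3 (boundary values fall in the intermediate class by convention).
    A ``near_boundary`` flag marks CVs within ``near_boundary_margin`` of a
    bound, where the classification should not be over-read.
    """
    lower, upper = bounds
    if not lower < upper:
        raise ValueError(f"cv bounds must be increasing, got {bounds}")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv < lower:
        cls = AssemblageClass.Type1
    elif cv <= upper:
        cls = AssemblageClass.Type2
    else:
        cls = AssemblageClass.Type3
    near = min(abs(cv - lower), abs(cv - upper)) <= near_boundary_margin
    return AssemblageType(value=cls, cv=float(cv), n_used=n_used, near_boundary=near)


def characterize_assemblage(
    prints: Sequence[PrintRecord],
    min_ridges: int = 6,
    outlier_threshold: float = 3.5,
    cv_bounds: tuple[float, float] = (0.09, 0.11),
) -> tuple[AssemblageType, dict]:
    """Full characterization: quality filter, outlier screen, CV, typing.

    Returns the :class:`AssemblageType` and a report dict with the CV,
    counts of filtered prints and removed outliers.
    """
    usable = filter_prints(prints, min_ridges)
    if len(usable) < 3:
        raise ValueError("too few usable prints to characterize the assemblage")
    mrbs = [p.mrb for p in usable]
    cleaned = remove_extreme_outliers(mrbs, threshold=outlier_threshold)
    cv = coefficient_of_variation(cleaned)
    atype = classify_assemblage(cv, bounds=cv_bounds, n_used=len(cleaned))
    report = {
        "cv": cv,
        "type": atype.value.name,
        "n_input": len(prints),
        "n_after_ridge_filter": len(usable),
        "n_used": len(cleaned),
        "n_outliers_removed": len(usable) - len(cleaned),
        "near_boundary": atype.near_boundary,
    }
    return atype, report
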