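"""Pipeline configuration: documented defaults, YAML overrides, echo.

A config file only needs the keys it changes; unknown keys are an error so
typos never silently fall back to defaults.  ``as_dict`` round-trips through
``load_config`` exactly (merge is idempotent), so the echoed config of a run
can be replayed verbatim.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .datatypes import FEMALE, MALE
from .growth import GrowthParams


@dataclass
class OutlierRule:
    method: str = "robust_z"  # median/MAD robust z-score
    threshold: float = 3.5


@dataclass
class MCMCConfig:
    n_chains: int = 10
    ess_target: float = 3000.0
    rhat_target: float = 1.01
    max_iterations: int = 64_000    # per chain, cumulative sampling draws
    warmup: int = 3000
    initial_draws: int = 4000       # sampling draws before the first check
    seed: Optional[int] = None
    n_temps: int = 4                # parallel-tempering levels per chain
    time_budget_s: Optional[float] = None  # stop extending past this wall time
    age_grid_size: int = 64         # Gauss-Legendre nodes per age component
    age_max: float = 100.0


@dataclass
class PriorConfig:
    """Hyperprior constants for the mixture model.

    Weakly informative by design: potter mean age most likely around 20
    (anything from ~5 to ~45 plausible), age SD favoring small values
    (anything up to ~35 plausible), flat sex ratio.
    """

    mu_age_mean: float = 20.0    # Gamma prior on per-sex mean age
    mu_age_sd: float = 10.0
    sd_age_scale: float = 15.0   # Half-normal prior on per-sex age SD
    growth_rel_sd: float = 0.10  # Normal prior SD for asym/r0, relative to center
    lrc_sd: float = 0.5          # Normal prior SD for lrc
    sigma_scale_mult: float = 2.0  # Half-normal scale for sigma = mult * default sigma


@dataclass
class PipelineConfig:
    min_ridges: int = 6
    scaling_percentile: float = 95.0
    cv_bounds: tuple = (0.09, 0.11)
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    age_class_bounds: tuple = (12.0, 20.0)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    growth_defaults: GrowthParams = field(default_factory=GrowthParams)
    comparator_coefficients: Optional[dict] = None  # None -> refit stand-ins
    kamod2_threshold: float = 14.9

    def __post_init__(self):
        lo, hi = self.cv_bounds
        if not lo < hi:
            raise ValueError(f"cv_bounds must be strictly increasing, got {self.cv_bounds}")
        if not 0 < self.scaling_percentile < 100:
            raise ValueError("scaling_percentile must be in (0, 100)")
        a, b = self.age_class_bounds
        if not 0 < a < b:
            raise ValueError("age_class_bounds must be increasing and positive")
        for name in ("min_ridges", "kamod2_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cv_bounds"] = list(self.cv_bounds)
        d["age_class_bounds"] = list(self.age_class_bounds)
        g = d["growth_defaults"]
        for key in ("asym", "r0", "lrc"):
            g[key] = {"female": g[key][FEMALE], "male": g[key][MALE]}
        return d


_SEX_KEYS = {"female": FEMALE, "male": MALE, "1": FEMALE, "2": MALE, 1: FEMALE, 2: MALE}


def _growth_from_dict(d: dict) -> GrowthParams:
    def persex(v):
        if isinstance(v, dict):
            return {_SEX_KEYS[k]: float(x) for k, x in v.items()}
        raise ValueError(f"per-sex growth field must be a mapping, got {v!r}")

    kwargs = {}
    for key in ("asym", "r0", "lrc"):
        if key in d:
            kwargs[key] = persex(d[key])
    if "sigma" in d:
        kwargs["sigma"] = float(d["sigma"])
    if "provenance" in d:
        kwargs["provenance"] = str(d["provenance"])
    base = GrowthParams()
    full = {
        "asym": dict(base.asym), "r0": dict(base.r0), "lrc": dict(base.lrc),
        "sigma": base.sigma, "provenance": base.provenance,
    }
    for key, val in kwargs.items():
        if isinstance(val, dict) and key in ("asym", "r0", "lrc"):
            full[key].update(val)
        else:
            full[key] = val
    unknown = set(d) - {"asym", "r0", "lrc", "sigma", "provenance"}
    if unknown:
        raise ValueError(f"unknown growth_defaults keys: {sorted(unknown)}")
    return GrowthParams(**full)


def _merge_dataclass(obj, overrides: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(obj)}
    unknown = set(overrides) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    updates = {}
    for key, val in overrides.items():
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            if isinstance(current, GrowthParams):
                updates[key] = _growth_from_dict(val)
            else:
                updates[key] = _merge_dataclass(current, val, f"{path}.{key}")
        elif key in ("cv_bounds", "age_class_bounds"):
            updates[key] = tuple(float(x) for x in val)
        else:
            updates[key] = val
    return dataclasses.replace(obj, **updates)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load the pipeline config; a missing/absent file yields full defaults.

    Partial files override only the named keys; unknown keys raise.
    """
    cfg = PipelineConfig()
    if path is None:
        return cfg
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    # the echoed dict uses female/male keys for growth; accept it back verbatim
    return _merge_dataclass(cfg, raw, "config")


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
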