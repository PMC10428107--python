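"""Bayesian mixture model over an assemblage's MRB distribution.

The observed mean ridge breadths are modelled as a two-component mixture:
each print belongs to a latent component (female/male in the two-sex
variants, younger/older age group in the one-sex variant), the component's
age distribution is gamma with moment-matched shape/rate (``alpha =
mu^2/sd^2``, ``beta = mu/sd^2``), and given age and component the observed
MRB is normal around the asymptotic growth curve with residual SD ``sigma``.

    MRB_i | age_i, sex_i ~ Normal(u_i, sigma),  u_i = growth(age_i, sex_i)
    age_i | sex_i        ~ Gamma(alpha_s, beta_s)
    sex_i                ~ Bernoulli(probMale)

Inference marginalizes the discrete component analytically and integrates
age with Gauss-Legendre quadrature on each component's own range
[mu - 10 sd, mu + 10 sd] (clipped to [0, age_max]), which resolves narrow
and broad age distributions equally well; per-print age/sex posteriors are
recovered from the mixture responsibilities.  Sampling is multi-chain
parallel-tempered adaptive Metropolis with a run-extend-check stopping
rule: chains run until every monitored parameter reaches the target
effective sample size and its Gelman-Rubin upper confidence bound falls
below the target.

Priors (all configurable through :class:`~ridgemix.config.PriorConfig`):
flat on the sex ratio; per-component mean age Gamma(mean 20, sd 10) — most
likely around 20, anything from ~5 to ~45 plausible; age SD half-normal
(scale 15) favoring small values with anything up to ~35 plausible; growth
parameters normal around the curve in effect with deliberately generous
spreads; sigma half-normal at twice its default.

Optionally, the print with the largest MRB is constrained to be an adult
man (``constrain_max_is_male``): men sit at the top of the MRB range, so
the constraint aids identifiability at little cost once the assemblage has
been scaled.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp

from .config import MCMCConfig, PipelineConfig, PriorConfig
from .datatypes import FEMALE, MALE
from .growth import GrowthParams, asymptotic_curve
from . import diagnostics

logger = logging.getLogger(__name__)

VARIANTS = ("two_sex_two_age", "two_sex_one_age", "one_sex_two_age")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Numerical floor on component age SD (years): quadrature cannot resolve
#: age spikes narrower than the node spacing, and sub-half-year workforce
#: age spreads are not meaningful.
SD_AGE_FLOOR = 0.5
MU_AGE_FLOOR = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """Which mixture variant to fit.

    ``two_sex_two_age`` is the standard model (independent age distribution
    per sex); ``two_sex_one_age`` shares one age distribution across sexes;
    ``one_sex_two_age`` assumes all-male potters split into two age groups
    (ordered by mean age for identifiability).
    """

    variant: str = "two_sex_two_age"
    constrain_max_is_male: bool = True
    name: Optional[str] = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    @property
    def label(self) -> str:
        return self.name or self.variant


@dataclass
class DemographyParams:
    """Population-level demographic parameters.

    ``mu_age``/``sd_age`` are keyed by component: sex (1=female, 2=male) in
    the two-sex variants, age group (1=younger, 2=older) in the one-sex
    variant, where ``group_weight`` is the mixture weight of the younger
    group and ``prob_male`` is fixed at 1.
    """

    prob_male: float
    mu_age: dict
    sd_age: dict
    group_weight: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.prob_male <= 1.0:
            raise ValueError("prob_male must lie in [0, 1]")
        for k in self.mu_age:
            if self.mu_age[k] <= 0 or self.sd_age[k] <= 0:
                raise ValueError("age means and SDs must be positive")

    @property
    def alpha(self) -> dict:
        return {k: self.mu_age[k] ** 2 / self.sd_age[k] ** 2 for k in self.mu_age}

    @property
    def beta(self) -> dict:
        return {k: self.mu_age[k] / self.sd_age[k] ** 2 for k in self.mu_age}


def _quadrature(n_nodes: int, age_max: float):
    """Gauss-Legendre nodes/log-weights on (0, age_max)."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    nodes = 0.5 * age_max * (x + 1.0)
    logw = np.log(0.5 * age_max * w)
    return nodes, logw


def _gl_base(n_nodes: int):
    """Base Gauss-Legendre rule on [-1, 1] for component-adapted ranges."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return x, np.log(w)


def _log_gamma_pdf(a: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    return alpha * math.log(beta) - gammaln(alpha) + (alpha - 1.0) * np.log(a) - beta * a


def _component_setup(demography: DemographyParams, growth_arrays, spec: ModelSpec):
    """Per-component (mu, sd, log weight, curve params) for the two mixture slots.

    Returns (log_weights[2], mus[2], sds[2], asym[2], r0[2], lrc[2],
    male_component_index).
    """
    asym, r0, lrc = growth_arrays
    if spec.variant == "one_sex_two_age":
        gw = demography.group_weight
        if gw is None:
            raise ValueError("one_sex_two_age requires group_weight")
        logw = np.log(np.clip([gw, 1.0 - gw], 1e-300, None))
        mus = np.array([demography.mu_age[1], demography.mu_age[2]])
        sds = np.array([demography.sd_age[1], demography.sd_age[2]])
        # both groups are male
        asym_c = np.array([asym[1], asym[1]])
        r0_c = np.array([r0[1], r0[1]])
        lrc_c = np.array([lrc[1], lrc[1]])
        return logw, mus, sds, asym_c, r0_c, lrc_c, None
    pm = demography.prob_male
    logw = np.log(np.clip([1.0 - pm, pm], 1e-300, None))
    if spec.variant == "two_sex_one_age":
        mu = demography.mu_age.get("shared", demography.mu_age.get(FEMALE))
        sd = demography.sd_age.get("shared", demography.sd_age.get(FEMALE))
        mus = np.array([mu, mu])
        sds = np.array([sd, sd])
    else:
        mus = np.array([demography.mu_age[FEMALE], demography.mu_age[MALE]])
        sds = np.array([demography.sd_age[FEMALE], demography.sd_age[MALE]])
    return logw, mus, sds, asym.copy(), r0.copy(), lrc.copy(), 1


def _component_log_joint(data, logw, mus, sds, asym, r0, lrc, sigma, nodes, lognw):
    """log of the (print, component, node) joint mass; shape (n, 2, J)."""
    alphas = mus**2 / sds**2
    betas = mus / sds**2
    inv_sigma = 1.0 / sigma
    const = -math.log(sigma) - _LOG_SQRT_2PI
    out = np.empty((len(data), 2, len(nodes)))
    for c in range(2):
        u = asymptotic_curve(nodes, asym[c], r0[c], lrc[c])  # (J,)
        log_age = _log_gamma_pdf(nodes, alphas[c], betas[c]) + lognw  # (J,)
        z = (data[:, None] - u[None, :]) * inv_sigma
        np.multiply(z, z, out=z)
        z *= -0.5
        z += (log_age + (logw[c] + const))[None, :]
        out[:, c, :] = z
    return out


#: Half-width of each component's quadrature range, in age-SD units.  The
#:  gamma density beyond ten SDs carries no appreciable mass.
_RANGE_SDS = 10.0

try:  # compiled likelihood kernel; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _loglik_kernel(data, gl_x, gl_logw, age_max, logw, mus, sds, asym,
                       r0, lrc, sigma, constrained, male_c):  # pragma: no cover - jit
        n = data.size
        J = gl_x.size
        const = -math.log(sigma) - 0.5 * math.log(2.0 * math.pi)
        inv_sigma = 1.0 / sigma
        # per-component node tables on the component's own age range
        u_tab = np.empty((2, J))
        la_tab = np.empty((2, J))
        for c in range(2):
            alpha = mus[c] * mus[c] / (sds[c] * sds[c])
            beta = mus[c] / (sds[c] * sds[c])
            base = alpha * math.log(beta) - math.lgamma(alpha)
            lo = mus[c] - 10.0 * sds[c]
            if lo < 0.0:
                lo = 0.0
            hi = mus[c] + 10.0 * sds[c]
            if hi > age_max:
                hi = age_max
            half = 0.5 * (hi - lo)
            mid = 0.5 * (hi + lo)
            log_half = math.log(half)
            for j in range(J):
                a = mid + half * gl_x[j]
                if a <= 0.0:
                    a = 1e-12
                la = (base + (alpha - 1.0) * math.log(a) - beta * a
                      + gl_logw[j] + log_half)
                u_tab[c, j] = (asym[c] + (r0[c] - asym[c])
                               * math.exp(-math.exp(lrc[c]) * a))
                la_tab[c, j] = la + logw[c] + const
        total = 0.0
        scratch = np.empty(2 * J)
        for i in range(n):
            x = data[i]
            c_lo = male_c if (i == constrained and male_c >= 0) else 0
            c_hi = male_c + 1 if (i == constrained and male_c >= 0) else 2
            m = -1e308
            idx = 0
            for c in range(c_lo, c_hi):
                for j in range(J):
                    z = (x - u_tab[c, j]) * inv_sigma
                    v = la_tab[c, j] - 0.5 * z * z
                    scratch[idx] = v
                    if v > m:
                        m = v
                    idx += 1
            s = 0.0
            thresh = m - 37.0  # below this the term is < 1e-16 of the max
            for j in range(idx):
                if scratch[j] > thresh:
                    s += math.exp(scratch[j] - m)
            total += m + math.log(s)
        return total

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _marginal_loglik(data, logw, mus, sds, asym, r0, lrc, sigma, gl_x, gl_logw,
                     age_max: float, constrained: Optional[int],
                     male_c: Optional[int]) -> float:
    """Marginal log-likelihood with component-adapted quadrature.

    Each component's age integral is taken on its own range [mu - 10 sd,
    mu + 10 sd] (clipped to [0, age_max]) so that arbitrarily concentrated
    age distributions are resolved exactly as well as broad ones — a fixed
    global grid under-resolves narrow components and can fabricate spurious
    posterior modes at sub-node-spacing age SDs.
    """
    alphas = mus**2 / sds**2
    betas = mus / sds**2
    inv_sigma = 1.0 / sigma
    const = -math.log(sigma) - _LOG_SQRT_2PI
    parts = []
    for c in range(2):
        lo = max(0.0, mus[c] - _RANGE_SDS * sds[c])
        hi = min(age_max, mus[c] + _RANGE_SDS * sds[c])
        half = 0.5 * (hi - lo)
        a = 0.5 * (hi + lo) + half * gl_x
        np.clip(a, 1e-12, None, out=a)
        log_age = _log_gamma_pdf(a, alphas[c], betas[c]) + gl_logw + math.log(half)
        u = asymptotic_curve(a, asym[c], r0[c], lrc[c])
        z = (data[:, None] - u[None, :]) * inv_sigma
        np.multiply(z, z, out=z)
        z *= -0.5
        z += (log_age + (logw[c] + const))[None, :]
        parts.append(z)
    per_print = _logsumexp_last(np.concatenate(parts, axis=1))
    if constrained is not None and male_c is not None:
        per_print[constrained] = _logsumexp_last(parts[male_c][constrained])
    return float(per_print.sum())


def _logsumexp_last(a: np.ndarray) -> np.ndarray:
    """logsumexp over the trailing axis; plain numpy (fast path)."""
    m = a.max(axis=-1)
    with np.errstate(divide="ignore"):
        return m + np.log(np.exp(a - m[..., None]).sum(axis=-1))


def _constrained_index(data: np.ndarray, spec: ModelSpec) -> Optional[int]:
    if not spec.constrain_max_is_male or spec.variant == "one_sex_two_age":
        return None
    # ties broken by input order: first print attaining the maximum
    return int(np.argmax(data))


def log_likelihood(
    demography: DemographyParams,
    growth: GrowthParams,
    data: Sequence[float],
    spec: ModelSpec = ModelSpec(),
    n_nodes: int = 200,
    age_max: float = 100.0,
) -> float:
    """Marginal log-likelihood of the scaled MRB data.

    The latent component is summed analytically and the age integral
    evaluated by Gauss-Legendre quadrature on (0, ``age_max``); the print
    with the largest MRB is restricted to the male component when the spec
    requests it.
    """
    x = np.asarray(list(data), dtype=float)
    if x.size == 0:
        raise ValueError("data must be nonempty")
    gl_x, gl_logw = _gl_base(n_nodes)
    logw, mus, sds, asym, r0, lrc, male_c = _component_setup(
        demography, growth.as_arrays(), spec
    )
    ll = _marginal_loglik(x, logw, mus, sds, asym, r0, lrc, growth.sigma,
                          gl_x, gl_logw, age_max,
                          _constrained_index(x, spec), male_c)
    if not np.isfinite(ll):
        raise FloatingPointError(
            "non-finite log-likelihood at valid parameters (quadrature underflow?)"
        )
    return ll


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def _log_halfnormal(x: float, scale: float) -> float:
    return 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2


def _log_normal(x: float, mu: float, sd: float) -> float:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI


def _log_gamma_scalar(x: float, alpha: float, beta: float) -> float:
    return alpha * math.log(beta) - gammaln(alpha) + (alpha - 1.0) * math.log(x) - beta * x


def log_prior(
    demography: DemographyParams,
    growth: GrowthParams,
    spec: ModelSpec = ModelSpec(),
    priors: PriorConfig | None = None,
    growth_centers: GrowthParams | None = None,
) -> float:
    """Joint log-prior (fully normalized, so it is usable in Bayes factors)."""
    pr = priors or PriorConfig()
    centers = growth_centers or GrowthParams()
    mu_shape = (pr.mu_age_mean / pr.mu_age_sd) ** 2
    mu_rate = pr.mu_age_mean / pr.mu_age_sd**2
    lp = 0.0
    if spec.variant == "one_sex_two_age":
        comps = [1, 2]
        # group weight flat on [0,1]; the iid base prior restricted to the
        # ordered half-space mu1 < mu2 must be renormalized (factor 2) for
        # the prior to integrate to 1 (matters for Bayes factors)
        lp += math.log(2.0)
        sexes = [MALE]
    elif spec.variant == "two_sex_one_age":
        comps = [FEMALE]  # single shared age distribution
        sexes = [FEMALE, MALE]
    else:
        comps = [FEMALE, MALE]
        sexes = [FEMALE, MALE]
    for c in comps:
        mu, sd = demography.mu_age[c], demography.sd_age[c]
        if sd < SD_AGE_FLOOR or mu < MU_AGE_FLOOR:
            return -np.inf
        lp += _log_gamma_scalar(mu, mu_shape, mu_rate)
        lp += _log_halfnormal(sd, pr.sd_age_scale)
    for s in sexes:
        if not (0 < growth.r0[s] < growth.asym[s]):
            return -np.inf
        lp += _log_normal(growth.asym[s], centers.asym[s], pr.growth_rel_sd * centers.asym[s])
        lp += _log_normal(growth.r0[s], centers.r0[s], pr.growth_rel_sd * centers.r0[s])
        lp += _log_normal(growth.lrc[s], centers.lrc[s], pr.lrc_sd)
    lp += _log_halfnormal(growth.sigma, pr.sigma_scale_mult * centers.sigma)
    return lp


def log_posterior(
    demography: DemographyParams,
    growth: GrowthParams,
    data: Sequence[float],
    spec: ModelSpec = ModelSpec(),
    priors: PriorConfig | None = None,
    growth_centers: GrowthParams | None = None,
    n_nodes: int = 200,
    age_max: float = 100.0,
) -> float:
    """Unnormalized log-posterior: marginal log-likelihood plus log-priors."""
    lp = log_prior(demography, growth, spec, priors, growth_centers)
    if not np.isfinite(lp):
        return -np.inf
    return lp + log_likelihood(demography, growth, data, spec, n_nodes, age_max)


# ---------------------------------------------------------------------------
# transformed-space density used by the samplers
# ---------------------------------------------------------------------------

class MixtureDensity:
    """Log-posterior of one model variant on unconstrained parameters.

    Handles the transform bookkeeping (logit mixture weights, log age
    moments and sigma, ordered means in the one-sex variant), exposes
    natural-scale views of draws, and computes mixture responsibilities.
    """

    def __init__(self, data, spec: ModelSpec, growth_centers: GrowthParams,
                 priors: PriorConfig | None = None, n_nodes: int = 200,
                 age_max: float = 100.0):
        self.data = np.asarray(list(data), dtype=float)
        if self.data.size == 0:
            raise ValueError("data must be nonempty")
        self.spec = spec
        self.centers = growth_centers
        self.priors = priors or PriorConfig()
        # component-adapted rule for the likelihood; a fixed grid (at least
        # 128 nodes) is kept for responsibilities, which need a common grid
        self.gl_x, self.gl_logw = _gl_base(n_nodes)
        self.nodes, self.lognw = _quadrature(max(n_nodes, 128), age_max)
        self.age_max = age_max
        self.constrained = _constrained_index(self.data, spec)
        if spec.variant == "one_sex_two_age":
            self._sexes = [MALE]
            self.param_names = [
                "logit_weight_young", "log_mu_age_1", "log_gap_mu",
                "log_sd_age_1", "log_sd_age_2",
                "asym_m", "r0_m", "lrc_m", "log_sigma",
            ]
            self.monitored_names = [
                "weight_young", "mu_age_1", "mu_age_2", "sd_age_1", "sd_age_2",
                "asym_m", "r0_m", "lrc_m", "sigma",
            ]
        elif spec.variant == "two_sex_one_age":
            self._sexes = [FEMALE, MALE]
            self.param_names = [
                "logit_prob_male", "log_mu_age", "log_sd_age",
                "asym_f", "asym_m", "r0_f", "r0_m", "lrc_f", "lrc_m", "log_sigma",
            ]
            self.monitored_names = [
                "prob_male", "mu_age", "sd_age",
                "asym_f", "asym_m", "r0_f", "r0_m", "lrc_f", "lrc_m", "sigma",
            ]
        else:
            self._sexes = [FEMALE, MALE]
            self.param_names = [
                "logit_prob_male", "log_mu_age_f", "log_mu_age_m",
                "log_sd_age_f", "log_sd_age_m",
                "asym_f", "asym_m", "r0_f", "r0_m", "lrc_f", "lrc_m", "log_sigma",
            ]
            self.monitored_names = [
                "prob_male", "mu_age_f", "mu_age_m", "sd_age_f", "sd_age_m",
                "asym_f", "asym_m", "r0_f", "r0_m", "lrc_f", "lrc_m", "sigma",
            ]
        self.dim = len(self.param_names)
        self._mu_shape = (self.priors.mu_age_mean / self.priors.mu_age_sd) ** 2
        self._mu_rate = self.priors.mu_age_mean / self.priors.mu_age_sd**2

    # -- transforms ---------------------------------------------------------

    def unpack(self, theta: np.ndarray):
        """theta -> (DemographyParams, GrowthParams-like tuple, sigma, log_jac)."""
        v = self.spec.variant
        t = np.asarray(theta, dtype=float)
        if v == "one_sex_two_age":
            gw = expit(t[0])
            mu1 = math.exp(t[1])
            mu2 = mu1 + math.exp(t[2])
            sd1, sd2 = math.exp(t[3]), math.exp(t[4])
            asym = {FEMALE: self.centers.asym[FEMALE], MALE: t[5]}
            r0 = {FEMALE: self.centers.r0[FEMALE], MALE: t[6]}
            lrc = {FEMALE: self.centers.lrc[FEMALE], MALE: t[7]}
            sigma = math.exp(t[8])
            jac = (math.log(max(gw * (1 - gw), 1e-300)) + t[1] + t[2]
                   + t[3] + t[4] + t[8])
            demo = DemographyParams(prob_male=1.0, mu_age={1: mu1, 2: mu2},
                                    sd_age={1: sd1, 2: sd2}, group_weight=gw)
        elif v == "two_sex_one_age":
            pm = expit(t[0])
            mu, sd = math.exp(t[1]), math.exp(t[2])
            asym = {FEMALE: t[3], MALE: t[4]}
            r0 = {FEMALE: t[5], MALE: t[6]}
            lrc = {FEMALE: t[7], MALE: t[8]}
            sigma = math.exp(t[9])
            jac = math.log(max(pm * (1 - pm), 1e-300)) + t[1] + t[2] + t[9]
            demo = DemographyParams(prob_male=pm,
                                    mu_age={"shared": mu, FEMALE: mu, MALE: mu},
                                    sd_age={"shared": sd, FEMALE: sd, MALE: sd})
        else:
            pm = expit(t[0])
            mu_f, mu_m = math.exp(t[1]), math.exp(t[2])
            sd_f, sd_m = math.exp(t[3]), math.exp(t[4])
            asym = {FEMALE: t[5], MALE: t[6]}
            r0 = {FEMALE: t[7], MALE: t[8]}
            lrc = {FEMALE: t[9], MALE: t[10]}
            sigma = math.exp(t[11])
            jac = (math.log(max(pm * (1 - pm), 1e-300))
                   + t[1] + t[2] + t[3] + t[4] + t[11])
            demo = DemographyParams(prob_male=pm,
                                    mu_age={FEMALE: mu_f, MALE: mu_m},
                                    sd_age={FEMALE: sd_f, MALE: sd_m})
        growth = GrowthParams(asym=asym, r0=r0, lrc=lrc, sigma=sigma,
                              provenance="draw") if _growth_valid(asym, r0, sigma) else None
        return demo, growth, sigma, jac

    def pack(self, demography: DemographyParams, growth: GrowthParams) -> np.ndarray:
        v = self.spec.variant
        if v == "one_sex_two_age":
            mu1, mu2 = demography.mu_age[1], demography.mu_age[2]
            return np.array([
                logit(demography.group_weight), math.log(mu1), math.log(mu2 - mu1),
                math.log(demography.sd_age[1]), math.log(demography.sd_age[2]),
                growth.asym[MALE], growth.r0[MALE], growth.lrc[MALE],
                math.log(growth.sigma),
            ])
        if v == "two_sex_one_age":
            mu = demography.mu_age.get("shared", demography.mu_age.get(FEMALE))
            sd = demography.sd_age.get("shared", demography.sd_age.get(FEMALE))
            return np.array([
                logit(demography.prob_male), math.log(mu), math.log(sd),
                growth.asym[FEMALE], growth.asym[MALE],
                growth.r0[FEMALE], growth.r0[MALE],
                growth.lrc[FEMALE], growth.lrc[MALE], math.log(growth.sigma),
            ])
        return np.array([
            logit(demography.prob_male),
            math.log(demography.mu_age[FEMALE]), math.log(demography.mu_age[MALE]),
            math.log(demography.sd_age[FEMALE]), math.log(demography.sd_age[MALE]),
            growth.asym[FEMALE], growth.asym[MALE],
            growth.r0[FEMALE], growth.r0[MALE],
            growth.lrc[FEMALE], growth.lrc[MALE], math.log(growth.sigma),
        ])

    # -- densities ----------------------------------------------------------

    def log_post_parts(self, theta: np.ndarray) -> tuple[float, float]:
        """(log prior + Jacobian, log likelihood); (-inf, -inf) off-support."""
        try:
            demo, growth, sigma, jac = self.unpack(theta)
        except (OverflowError, ValueError):
            return -np.inf, -np.inf
        if growth is None:
            return -np.inf, -np.inf
        lp = log_prior(demo, growth, self.spec, self.priors, self.centers)
        if not np.isfinite(lp):
            return -np.inf, -np.inf
        logw, mus, sds, asym, r0, lrc, male_c = _component_setup(
            demo, growth.as_arrays(), self.spec
        )
        if _HAVE_NUMBA:
            ll = _loglik_kernel(
                self.data, self.gl_x, self.gl_logw, self.age_max, logw, mus,
                sds, asym, r0, lrc, sigma,
                -1 if self.constrained is None else self.constrained,
                -1 if male_c is None else male_c)
        else:
            ll = _marginal_loglik(self.data, logw, mus, sds, asym, r0, lrc,
                                  sigma, self.gl_x, self.gl_logw, self.age_max,
                                  self.constrained, male_c)
        if not np.isfinite(ll):
            return -np.inf, -np.inf
        return lp + jac, ll

    def log_post(self, theta: np.ndarray) -> float:
        lp, ll = self.log_post_parts(theta)
        return lp + ll if np.isfinite(lp) else -np.inf

    def log_joint_responsibility(self, theta: np.ndarray) -> np.ndarray:
        """Normalized per-print (component, age-node) posterior mass, (n,2,J)."""
        demo, growth, sigma, _ = self.unpack(theta)
        logw, mus, sds, asym, r0, lrc, male_c = _component_setup(
            demo, growth.as_arrays(), self.spec
        )
        lj = _component_log_joint(self.data, logw, mus, sds, asym, r0, lrc,
                                  sigma, self.nodes, self.lognw)
        if self.constrained is not None and male_c is not None:
            female_c = 1 - male_c
            lj[self.constrained, female_c, :] = -np.inf
        norm = logsumexp(lj, axis=(1, 2), keepdims=True)
        return np.exp(lj - norm)

    # -- natural-scale views -------------------------------------------------

    def natural(self, thetas: np.ndarray) -> dict:
        """Map an (..., dim) array of draws to named natural-scale arrays."""
        t = np.asarray(thetas, dtype=float)
        v = self.spec.variant
        out = {}
        if v == "one_sex_two_age":
            out["weight_young"] = expit(t[..., 0])
            out["mu_age_1"] = np.exp(t[..., 1])
            out["mu_age_2"] = out["mu_age_1"] + np.exp(t[..., 2])
            out["sd_age_1"] = np.exp(t[..., 3])
            out["sd_age_2"] = np.exp(t[..., 4])
            out["asym_m"], out["r0_m"], out["lrc_m"] = (t[..., 5], t[..., 6], t[..., 7])
            out["sigma"] = np.exp(t[..., 8])
        elif v == "two_sex_one_age":
            out["prob_male"] = expit(t[..., 0])
            out["mu_age"] = np.exp(t[..., 1])
            out["sd_age"] = np.exp(t[..., 2])
            for i, name in enumerate(["asym_f", "asym_m", "r0_f", "r0_m",
                                      "lrc_f", "lrc_m"]):
                out[name] = t[..., 3 + i]
            out["sigma"] = np.exp(t[..., 9])
        else:
            out["prob_male"] = expit(t[..., 0])
            out["mu_age_f"] = np.exp(t[..., 1])
            out["mu_age_m"] = np.exp(t[..., 2])
            out["sd_age_f"] = np.exp(t[..., 3])
            out["sd_age_m"] = np.exp(t[..., 4])
            for i, name in enumerate(["asym_f", "asym_m", "r0_f", "r0_m",
                                      "lrc_f", "lrc_m"]):
                out[name] = t[..., 5 + i]
            out["sigma"] = np.exp(t[..., 11])
        return out

    def swap_components(self, theta: np.ndarray) -> Optional[np.ndarray]:
        """Label-swap involution: exchange the two components' demography.

        For the two-sex variants this proposes "the women were really the
        men" (prob_male -> 1 - prob_male, per-sex age moments exchanged,
        growth curves untouched): a symmetric deterministic proposal with
        unit Jacobian that lets chains cross the near-exchangeable ridge
        when the data cannot tell the components apart.  Not applicable to
        the order-constrained one-sex variant.
        """
        v = self.spec.variant
        t = np.array(theta, dtype=float)
        if v == "two_sex_two_age":
            t[0] = -t[0]
            t[[1, 2]] = t[[2, 1]]
            t[[3, 4]] = t[[4, 3]]
            return t
        if v == "two_sex_one_age":
            t[0] = -t[0]
            return t
        return None

    def sample_init(self, rng: np.random.Generator) -> np.ndarray:
        """Over-dispersed start: an independent draw from the priors."""
        pr = self.priors
        for _ in range(200):
            mu = {}
            sd = {}
            for c in (1, 2):
                mu[c] = max(rng.gamma(self._mu_shape, 1.0 / self._mu_rate), 2.0)
                sd[c] = max(abs(rng.normal(0.0, pr.sd_age_scale)), 1.0)
            if self.spec.variant == "one_sex_two_age":
                mu1, mu2 = sorted((mu[1], mu[2]))
                if mu2 - mu1 < 0.5:
                    mu2 = mu1 + 0.5
                demo = DemographyParams(prob_male=1.0, mu_age={1: mu1, 2: mu2},
                                        sd_age=sd, group_weight=rng.uniform(0.05, 0.95))
            elif self.spec.variant == "two_sex_one_age":
                demo = DemographyParams(prob_male=rng.uniform(0.05, 0.95),
                                        mu_age={"shared": mu[1], FEMALE: mu[1], MALE: mu[1]},
                                        sd_age={"shared": sd[1], FEMALE: sd[1], MALE: sd[1]})
            else:
                demo = DemographyParams(prob_male=rng.uniform(0.05, 0.95),
                                        mu_age={FEMALE: mu[1], MALE: mu[2]},
                                        sd_age=sd)
            asym, r0, lrc = {}, {}, {}
            for s in (FEMALE, MALE):
                asym[s] = self.centers.asym[s] * (1 + 0.05 * rng.standard_normal())
                r0[s] = abs(self.centers.r0[s] * (1 + 0.05 * rng.standard_normal()))
                lrc[s] = self.centers.lrc[s] + 0.25 * rng.standard_normal()
                if r0[s] >= asym[s]:
                    r0[s] = 0.5 * asym[s]
            sigma = max(abs(rng.normal(0.0, self.centers.sigma)), 0.25 * self.centers.sigma)
            growth = GrowthParams(asym=asym, r0=r0, lrc=lrc, sigma=sigma,
                                  provenance="init")
            theta = self.pack(demo, growth)
            if np.isfinite(self.log_post(theta)):
                return theta
        raise RuntimeError("could not find a finite-posterior initial state")


def _growth_valid(asym, r0, sigma) -> bool:
    return (sigma > 0 and all(0 < r0[s] < asym[s] for s in (FEMALE, MALE)))


# ---------------------------------------------------------------------------
# adaptive Metropolis sampler
# ---------------------------------------------------------------------------

#: Inverse-temperature ladder for within-chain parallel tempering; only the
#: cold level (beta = 1) is recorded.  Geometric spacing keeps the swap
#: acceptance between adjacent levels roughly even.
_PT_BETAS = (1.0, 0.55, 0.3, 0.15)


class _Level:
    """One tempered level: adaptive random-walk Metropolis state."""

    def __init__(self, density: MixtureDensity, rng: np.random.Generator,
                 init_scales: np.ndarray, beta: float):
        self.beta = beta
        self.x = density.sample_init(rng)
        self.lp_prior, self.lp_lik = density.log_post_parts(self.x)
        d = density.dim
        self.mean = self.x.copy()
        self.cov = np.diag(init_scales**2)
        self.count = 1
        self.log_step = math.log(2.38 / math.sqrt(d)) - 1.0
        self.chol = np.linalg.cholesky(self.cov + 1e-12 * np.eye(d))


class _Chain:
    """One parallel-tempered chain of adaptive Metropolis levels.

    The mixture posterior at realistic sample sizes is multimodal (label
    mirrors and competing age/sex assignments); hot levels (likelihood
    tempered by beta < 1) cross between basins and feed states to the cold
    level through adjacent-level swaps.  Each level adapts its own proposal
    covariance (Haario-style, step size tuned toward 23% acceptance) during
    warmup and freezes afterwards; label-swap moves hop between
    mirror-image component labellings during sampling.  Only cold-level
    draws are recorded.
    """

    def __init__(self, density: MixtureDensity, rng: np.random.Generator,
                 init_scales: np.ndarray, betas=_PT_BETAS):
        self.density = density
        self.rng = rng
        self.levels = [_Level(density, rng, init_scales, b) for b in betas]
        self.adapting = True
        self.draws: list[np.ndarray] = []

    @property
    def x(self):
        return self.levels[0].x

    def _step_level(self, lv: _Level, t: int):
        if not self.adapting and self.rng.uniform() < 0.15:
            swapped = self.density.swap_components(lv.x)
            if swapped is not None:
                pp, pl = self.density.log_post_parts(swapped)
                cur = lv.lp_prior + lv.beta * lv.lp_lik
                if math.log(self.rng.uniform()) < (pp + lv.beta * pl) - cur:
                    lv.x, lv.lp_prior, lv.lp_lik = swapped, pp, pl
        z = self.rng.standard_normal(self.density.dim)
        prop = lv.x + math.exp(lv.log_step) * (lv.chol @ z)
        pp, pl = self.density.log_post_parts(prop)
        cur = lv.lp_prior + lv.beta * lv.lp_lik
        new = pp + lv.beta * pl if np.isfinite(pp) else -np.inf
        acc = math.log(self.rng.uniform()) < new - cur
        if acc:
            lv.x, lv.lp_prior, lv.lp_lik = prop, pp, pl
        if self.adapting:
            lv.log_step += ((1.0 if acc else 0.0) - 0.234) / (t + 10) ** 0.6
            lv.count += 1
            delta = lv.x - lv.mean
            lv.mean += delta / lv.count
            lv.cov += (np.outer(delta, lv.x - lv.mean) - lv.cov) / lv.count

    def _temperature_swaps(self):
        for a in range(len(self.levels) - 1):
            lo, hi = self.levels[a], self.levels[a + 1]  # lo is colder
            log_acc = (lo.beta - hi.beta) * (hi.lp_lik - lo.lp_lik)
            if math.log(self.rng.uniform()) < log_acc:
                lo.x, hi.x = hi.x, lo.x
                lo.lp_prior, hi.lp_prior = hi.lp_prior, lo.lp_prior
                lo.lp_lik, hi.lp_lik = hi.lp_lik, lo.lp_lik

    def _sweep(self, t: int):
        for lv in self.levels:
            self._step_level(lv, t)
        self._temperature_swaps()

    def warmup(self, n: int):
        d = self.density.dim
        self.adapting = True
        for t in range(n):
            if t == n // 3:
                # drop the transient's imprint on the covariance estimates
                for lv in self.levels:
                    lv.count = 2 * d
            if t >= 100 and t % 50 == 0:
                for lv in self.levels:
                    lv.chol = np.linalg.cholesky(lv.cov + 1e-10 * np.eye(d))
            self._sweep(t)
        for lv in self.levels:
            lv.chol = np.linalg.cholesky(lv.cov + 1e-10 * np.eye(d))
        self.adapting = False

    def sample(self, n: int):
        for _ in range(n):
            self._sweep(0)
            self.draws.append(self.levels[0].x.copy())


@dataclass
class PosteriorTraces:
    """Multi-chain MCMC output plus everything needed to summarize it."""

    thetas: np.ndarray              # (chain, draw, dim), transformed scale
    monitored: dict                 # name -> (chain, draw) natural-scale arrays
    density: MixtureDensity
    spec: ModelSpec
    seed: Optional[int]
    converged: bool
    n_chains: int
    n_draws: int                    # sampling draws per chain at termination
    ess: dict = field(default_factory=dict)
    rhat_upper: dict = field(default_factory=dict)

    @property
    def monitored_names(self):
        return list(self.monitored)

    def diagnostics_report(self) -> dict:
        return {
            "converged": self.converged,
            "n_chains": self.n_chains,
            "n_draws_per_chain": self.n_draws,
            "seed": self.seed,
            "ess": {k: float(v) for k, v in self.ess.items()},
            "rhat_upper": {k: float(v) for k, v in self.rhat_upper.items()},
        }


def _init_proposal_scales(density: MixtureDensity) -> np.ndarray:
    scales = []
    for name in density.param_names:
        if name.startswith("logit"):
            scales.append(0.5)
        elif name.startswith(("log_mu", "log_gap", "log_sd")):
            scales.append(0.3)
        elif name.startswith(("asym", "r0")):
            scales.append(0.02)
        elif name.startswith("lrc"):
            scales.append(0.15)
        else:  # log_sigma
            scales.append(0.2)
    return 0.3 * np.array(scales)


def sample_posterior(
    data: Sequence[float],
    spec: ModelSpec = ModelSpec(),
    growth: GrowthParams | None = None,
    config: PipelineConfig | MCMCConfig | None = None,
    seed: Optional[int] = None,
) -> PosteriorTraces:
    """Fit the mixture by multi-chain adaptive Metropolis with the
    run-extend-check stopping rule.

    Chains start from independent prior draws, adapt during warmup, then
    sample in doubling blocks; after each block the effective sample size
    and split-chain Gelman-Rubin upper bound of every monitored parameter
    are checked against the configured targets (defaults: ESS > 3000 and
    upper bound <= 1.01 with 10 chains).  If ``max_iterations`` draws per
    chain are reached first, traces are returned with ``converged=False``
    and a loud warning.
    """
    if isinstance(config, PipelineConfig):
        mcmc, priors, centers = config.mcmc, config.priors, config.growth_defaults
    else:
        mcmc = config or MCMCConfig()
        priors = PriorConfig()
        centers = GrowthParams()
    if growth is not None:
        centers = growth
    if seed is None:
        seed = mcmc.seed if mcmc.seed is not None else 0
    density = MixtureDensity(data, spec, centers, priors,
                             n_nodes=mcmc.age_grid_size, age_max=mcmc.age_max)
    if mcmc.n_chains < 2:
        raise ValueError("need at least 2 chains for convergence diagnostics")
    betas = _PT_BETAS[:max(1, min(getattr(mcmc, "n_temps", 4), len(_PT_BETAS)))]
    seq = np.random.SeedSequence(seed)
    chains = [
        _Chain(density, np.random.default_rng(child), _init_proposal_scales(density),
               betas=betas)
        for child in seq.spawn(mcmc.n_chains)
    ]
    for ch in chains:
        ch.warmup(mcmc.warmup)

    import time as _time
    t_start = _time.monotonic()
    block = mcmc.initial_draws
    total = 0
    converged = False
    ess: dict = {}
    rhat: dict = {}
    budget = getattr(mcmc, "time_budget_s", None)
    while True:
        for ch in chains:
            ch.sample(block)
        total += block
        thetas = np.stack([np.asarray(ch.draws) for ch in chains])  # (C, T, d)
        monitored = density.natural(thetas)
        ess = {k: diagnostics.effective_sample_size(v) for k, v in monitored.items()}
        rhat = {k: diagnostics.gelman_rubin_upper(v) for k, v in monitored.items()}
        ok_ess = all(v > mcmc.ess_target for v in ess.values())
        ok_rhat = all(v <= mcmc.rhat_target for v in rhat.values())
        if ok_ess and ok_rhat:
            converged = True
            break
        # extend by 75% per round: close to doubling's geometric efficiency
        # with less overshoot once the targets are near
        next_block = min(max(int(0.75 * total), mcmc.initial_draws),
                         mcmc.max_iterations - total)
        elapsed = _time.monotonic() - t_start
        projected = elapsed * (1.0 + next_block / total)  # after one more block
        if total >= mcmc.max_iterations or (budget is not None
                                            and projected > budget):
            logger.warning(
                "sample_posterior: NOT CONVERGED after %d draws/chain "
                "(min ESS %.0f, max R-hat upper %.4f)",
                total, min(ess.values()), max(rhat.values()),
            )
            break
        block = next_block
    return PosteriorTraces(
        thetas=thetas, monitored=monitored, density=density, spec=spec,
        seed=seed, converged=converged, n_chains=mcmc.n_chains, n_draws=total,
        ess=ess, rhat_upper=rhat,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

_QUANTILES = (2.5, 25.0, 50.0, 75.0, 97.5)


def summarize_population(traces: PosteriorTraces) -> pd.DataFrame:
    """Posterior summary (mean, median, central quantiles) of the population
    parameters, with the derived gamma shape/rate appended."""
    rows = {}
    flat = {k: np.asarray(v).reshape(-1) for k, v in traces.monitored.items()}
    for mu_key in [k for k in flat if k.startswith("mu_age")]:
        suffix = mu_key[len("mu_age"):]
        sd_key = "sd_age" + suffix
        if sd_key in flat:
            flat["alpha" + suffix] = flat[mu_key] ** 2 / flat[sd_key] ** 2
            flat["beta" + suffix] = flat[mu_key] / flat[sd_key] ** 2
    for name, draws in flat.items():
        qs = np.percentile(draws, _QUANTILES)
        rows[name] = {
            "mean": draws.mean(), "median": qs[2],
            "q2.5": qs[0], "q25": qs[1], "q75": qs[3], "q97.5": qs[4],
        }
    return pd.DataFrame(rows).T


def individual_posteriors(traces: PosteriorTraces, max_draws: int = 300) -> dict:
    """Per-print posterior over (component, age), averaged across retained draws.

    Returns ``{"joint": (n, 2, J), "age_grid": (J,), "p_male": (n,),
    "age_mean": (n,), "age_lo": (n,), "age_hi": (n,)}``; component index 1 is
    male in two-sex variants (both components male in the one-sex variant).
    """
    density = traces.density
    thetas = traces.thetas.reshape(-1, density.dim)
    if len(thetas) > max_draws:
        idx = np.linspace(0, len(thetas) - 1, max_draws).astype(int)
        thetas = thetas[idx]
    joint = np.zeros((density.data.size, 2, density.nodes.size))
    for theta in thetas:
        joint += density.log_joint_responsibility(theta)
    joint /= len(thetas)
    age_dist = joint.sum(axis=1)  # (n, J)
    age_mean = age_dist @ density.nodes
    cdf = np.cumsum(age_dist, axis=1)
    lo = density.nodes[np.argmax(cdf >= 0.025, axis=1)]
    hi = density.nodes[np.argmax(cdf >= 0.975, axis=1)]
    if traces.spec.variant == "one_sex_two_age":
        p_male = np.ones(density.data.size)
    else:
        p_male = joint[:, 1, :].sum(axis=1)
    return {
        "joint": joint, "age_grid": density.nodes, "p_male": p_male,
        "age_mean": age_mean, "age_lo": lo, "age_hi": hi,
    }


def summarize_individuals(traces: PosteriorTraces, data=None,
                          max_draws: int = 300) -> pd.DataFrame:
    """Per-print table: posterior P(male), posterior mean age, 95% age interval."""
    post = individual_posteriors(traces, max_draws=max_draws)
    mrbs = traces.density.data if data is None else np.asarray(list(data), float)
    return pd.DataFrame({
        "mrb": mrbs,
        "p_male": post["p_male"],
        "age_mean": post["age_mean"],
        "age_q2.5": post["age_lo"],
        "age_q97.5": post["age_hi"],
    })
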