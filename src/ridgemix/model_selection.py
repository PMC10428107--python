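"""Bayes-factor model selection via a product-space supermodel.

Competing mixture variants are combined into one augmented model carrying a
categorical model index (Carlin-Chib construction) and fitted
simultaneously: when a model is active its parameters move under their own
posterior, when inactive its demography block drifts under a *pseudo-prior*
fitted to a preliminary single-model run.  The index's posterior visit
frequencies give posterior model probabilities, and hence Bayes factors for
every pair of models; with equal model priors the comparison has the usual
built-in preference for simpler models.

The growth curve (per-sex Asym/R0/lrc) and the residual SD sigma mean the
same thing under every variant and carry the same prior, so they live in a
single block shared across the product space; only each variant's
demography parameters (sex ratio / mixture weight and age moments) are
model-specific.  Keeping the linking pseudo-priors low-dimensional is what
keeps the index switching rate healthy.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .config import MCMCConfig, PipelineConfig
from .datatypes import FEMALE, MALE
from .growth import GrowthParams
from .mixture import MixtureDensity, ModelSpec, sample_posterior

logger = logging.getLogger(__name__)

#: Shared-block layout: female/male growth curves plus log sigma.
_PHI_NAMES = ("asym_f", "asym_m", "r0_f", "r0_m", "lrc_f", "lrc_m", "log_sigma")


@dataclass
class ModelComparisonResult:
    model_ids: list
    posterior_prob: np.ndarray
    prior_prob: np.ndarray
    bayes_factors: np.ndarray           # [i, j] = BF of model i over model j
    index_trace_diagnostics: dict       # per-chain switching rates etc.
    n_index_draws: int

    def __post_init__(self):
        total = float(np.sum(self.posterior_prob))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior probabilities must sum to 1, got {total}")

    def as_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "posterior_prob": [float(p) for p in self.posterior_prob],
            "prior_prob": [float(p) for p in self.prior_prob],
            "bayes_factors": self.bayes_factors.tolist(),
            "index_trace_diagnostics": self.index_trace_diagnostics,
            "n_index_draws": self.n_index_draws,
        }


class _PseudoPrior:
    """Moment-matched multivariate normal linking density."""

    def __init__(self, draws: np.ndarray, inflate: float = 1.15):
        self.mean = draws.mean(axis=0)
        d = draws.shape[1]
        cov = np.cov(draws.T) if d > 1 else np.atleast_2d(np.var(draws))
        cov = inflate**2 * cov + 1e-10 * np.eye(d)
        self.chol = np.linalg.cholesky(cov)
        self._log_det = 2.0 * np.sum(np.log(np.diag(self.chol)))
        self._dim = d

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.mean + self.chol @ rng.standard_normal(self._dim)

    def logpdf(self, x: np.ndarray) -> float:
        y = solve_triangular(self.chol, x - self.mean, lower=True)
        return float(-0.5 * (y @ y) - 0.5 * self._log_det
                     - 0.5 * self._dim * math.log(2.0 * math.pi))


def _canonicalize(density, draws: np.ndarray) -> np.ndarray:
    """Fold label-swap mirror draws onto the majority labelling.

    The single-model sampler hops between the two equivalent component
    labellings; a moment-matched normal fit across both mirror modes would
    track neither.  For the standard two-sex variant the labelling is
    identified by the sign of (log mu_f - log mu_m): minority-orientation
    draws are swapped onto the majority side before fitting.
    """
    if density.spec.variant != "two_sex_two_age":
        return draws
    delta = draws[:, 1] - draws[:, 2]
    majority_positive = np.mean(delta > 0) >= 0.5
    out = draws.copy()
    flip = (delta <= 0) if majority_positive else (delta > 0)
    for i in np.where(flip)[0]:
        out[i] = density.swap_components(out[i])
    return out


def _blocks(density: MixtureDensity):
    """(demography dim, phi -> theta index map) for one variant's layout."""
    v = density.spec.variant
    if v == "two_sex_two_age":
        return 5, {i: 5 + i for i in range(7)}
    if v == "two_sex_one_age":
        return 3, {i: 3 + i for i in range(7)}
    # one_sex_two_age: male curve + sigma only
    return 5, {1: 5, 3: 6, 5: 7, 6: 8}


def _embed(demo: np.ndarray, phi: np.ndarray, demo_dim: int, phi_map: dict,
           total_dim: int) -> np.ndarray:
    theta = np.empty(total_dim)
    theta[:demo_dim] = demo
    for pi, ti in phi_map.items():
        theta[ti] = phi[pi]
    return theta


def _growth_logprior_part(phi: np.ndarray, phi_map: dict, centers: GrowthParams,
                          priors) -> float:
    """The model's own growth/sigma prior terms (to subtract from log_post:
    the shared block must not tilt the index update)."""
    c_mean = {0: centers.asym[FEMALE], 1: centers.asym[MALE],
              2: centers.r0[FEMALE], 3: centers.r0[MALE],
              4: centers.lrc[FEMALE], 5: centers.lrc[MALE]}
    c_sd = {0: priors.growth_rel_sd * centers.asym[FEMALE],
            1: priors.growth_rel_sd * centers.asym[MALE],
            2: priors.growth_rel_sd * centers.r0[FEMALE],
            3: priors.growth_rel_sd * centers.r0[MALE],
            4: priors.lrc_sd, 5: priors.lrc_sd}
    lp = 0.0
    for pi in phi_map:
        if pi == 6:
            sigma = math.exp(phi[6])
            scale = priors.sigma_scale_mult * centers.sigma
            lp += (0.5 * math.log(2.0 / math.pi) - math.log(scale)
                   - 0.5 * (sigma / scale) ** 2 + phi[6])  # prior + log-jac
        else:
            lp += (-0.5 * ((phi[pi] - c_mean[pi]) / c_sd[pi]) ** 2
                   - math.log(c_sd[pi]) - 0.5 * math.log(2.0 * math.pi))
    return lp


def _refresh_inert_phi(phi: np.ndarray, phi_map: dict, centers: GrowthParams,
                       priors, rng: np.random.Generator) -> None:
    """Gibbs-refresh shared-block entries the active model does not use
    (their full conditional is just the prior)."""
    inert = [i for i in range(7) if i not in phi_map]
    if not inert:
        return
    for _ in range(50):
        cand = phi.copy()
        for pi in inert:
            if pi in (0, 1):
                c = centers.asym[FEMALE if pi == 0 else MALE]
                cand[pi] = rng.normal(c, priors.growth_rel_sd * c)
            elif pi in (2, 3):
                c = centers.r0[FEMALE if pi == 2 else MALE]
                cand[pi] = rng.normal(c, priors.growth_rel_sd * c)
            else:
                c = centers.lrc[FEMALE if pi == 4 else MALE]
                cand[pi] = rng.normal(c, priors.lrc_sd)
        # keep the support constraint 0 < r0 < asym per sex
        if 0 < cand[2] < cand[0] and 0 < cand[3] < cand[1]:
            phi[:] = cand
            return


def _pilot_mcmc(mcmc: MCMCConfig, ess_target: float, n_chains: int) -> MCMCConfig:
    return dataclasses.replace(
        mcmc, n_chains=n_chains, ess_target=ess_target, rhat_target=1.2,
        warmup=2500, initial_draws=2000, max_iterations=8000,
    )


def run_supermodel(
    data: Sequence[float],
    specs: Sequence[ModelSpec],
    growth: GrowthParams | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    prior_prob: Optional[Sequence[float]] = None,
    n_chains: int = 4,
    n_iter: int = 2500,
    warmup: int = 300,
    pilot_ess_target: float = 150.0,
    pilot_chains: int = 3,
    mh_steps: int = 2,
) -> ModelComparisonResult:
    """Fit all ``specs`` simultaneously and return posterior model probabilities.

    Pseudo-priors for each variant's demography block come from
    moment-matching a preliminary single-model run; the shared growth/sigma
    block moves under the active model.  The model index is Gibbs-updated
    every sweep (each variant's density evaluated at its current block), so
    switching is healthy whenever the pseudo-priors roughly track the
    single-model posteriors.  Raises if the index never switches in any chain.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    cfg = config or PipelineConfig()
    centers = growth or cfg.growth_defaults
    priors = cfg.priors
    k_models = len(specs)
    if prior_prob is None:
        model_priors = np.full(k_models, 1.0 / k_models)
    else:
        model_priors = np.asarray(prior_prob, dtype=float)
        model_priors = model_priors / model_priors.sum()

    # --- pilot runs: pseudo-priors + frozen proposals ----------------------
    densities, pseudo, proposals, blocks = [], [], [], []
    phi_init = None
    for i, spec in enumerate(specs):
        pilot = sample_posterior(
            data, spec, centers,
            config=_pilot_mcmc(cfg.mcmc, pilot_ess_target, pilot_chains),
            seed=seed * 1000 + 7 * i + 1,
        )
        den = pilot.density
        flat = _canonicalize(den, pilot.thetas.reshape(-1, den.dim))
        demo_dim, phi_map = _blocks(den)
        densities.append(den)
        blocks.append((demo_dim, phi_map))
        pseudo.append(_PseudoPrior(flat[:, :demo_dim]))
        proposals.append((2.38 / math.sqrt(den.dim)) * 0.8 * np.linalg.cholesky(
            np.cov(flat.T) + 1e-10 * np.eye(den.dim)))
        if i == 0:
            mean = flat.mean(axis=0)
            phi_init = np.zeros(7)
            for pi, ti in phi_map.items():
                phi_init[pi] = mean[ti]
            # entries the first model lacks: start at the prior centers
            for pi in range(7):
                if pi not in phi_map:
                    defaults = {0: centers.asym[FEMALE], 1: centers.asym[MALE],
                                2: centers.r0[FEMALE], 3: centers.r0[MALE],
                                4: centers.lrc[FEMALE], 5: centers.lrc[MALE],
                                6: math.log(centers.sigma)}
                    phi_init[pi] = defaults[pi]

    # --- product-space chains ---------------------------------------------
    seq = np.random.SeedSequence(seed)
    index_traces, switch_rates = [], []
    for child in seq.spawn(n_chains):
        rng = np.random.default_rng(child)
        phi = phi_init.copy()
        demos = [ps.mean.copy() for ps in pseudo]
        k = int(rng.integers(k_models))
        trace, switches = [], 0
        for t in range(warmup + n_iter):
            demo_dim, phi_map = blocks[k]
            den = densities[k]
            # active model: joint MH on (demography, shared block)
            theta = _embed(demos[k], phi, demo_dim, phi_map, den.dim)
            logp = den.log_post(theta)
            for _ in range(mh_steps):
                prop = theta + proposals[k] @ rng.standard_normal(den.dim)
                lp = den.log_post(prop)
                if math.log(rng.uniform()) < lp - logp:
                    theta, logp = prop, lp
            demos[k] = theta[:demo_dim].copy()
            for pi, ti in phi_map.items():
                phi[pi] = theta[ti]
            _refresh_inert_phi(phi, phi_map, centers, priors, rng)
            # inactive demography blocks: exact Gibbs from the pseudo-priors
            for j in range(k_models):
                if j != k:
                    demos[j] = pseudo[j].sample(rng)
            # Gibbs update of the model index
            logits = np.empty(k_models)
            for j in range(k_models):
                dd, pm = blocks[j]
                th_j = _embed(demos[j], phi, dd, pm, densities[j].dim)
                logits[j] = (math.log(model_priors[j])
                             + densities[j].log_post(th_j)
                             - _growth_logprior_part(phi, pm, centers, priors)
                             - pseudo[j].logpdf(demos[j]))
            logits -= logits.max()
            probs = np.exp(logits)
            probs /= probs.sum()
            new_k = int(rng.choice(k_models, p=probs))
            if t >= warmup:
                trace.append(new_k)
                if new_k != k:
                    switches += 1
            k = new_k
        index_traces.append(np.array(trace))
        switch_rates.append(switches / n_iter)

    all_idx = np.concatenate(index_traces)
    counts = np.bincount(all_idx, minlength=k_models).astype(float)
    if all(r == 0.0 for r in switch_rates):
        raise RuntimeError(
            "supermodel index never switched in any chain; recalibrate the "
            "pseudo-priors (longer pilot runs) before trusting model probabilities"
        )
    post = counts / counts.sum()
    n_total = int(counts.sum())
    bf = _bayes_factor_matrix(post, model_priors, n_total)
    return ModelComparisonResult(
        model_ids=[s.label for s in specs],
        posterior_prob=post,
        prior_prob=model_priors,
        bayes_factors=bf,
        index_trace_diagnostics={
            "switch_rate_per_chain": [float(r) for r in switch_rates],
            "visit_counts": counts.tolist(),
        },
        n_index_draws=n_total,
    )


def _bayes_factor_matrix(post: np.ndarray, priors: np.ndarray, n_total: int) -> np.ndarray:
    # a never-visited model gets probability floored at 1/n_total: the BF is
    # then a bound on what the trace length can resolve, not infinity
    floor = 1.0 / max(n_total, 1)
    p = np.clip(post, floor, None)
    k = len(post)
    bf = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            bf[i, j] = (p[i] / p[j]) * (priors[j] / priors[i])
    return bf


def bayes_factor(result: ModelComparisonResult, i: int, j: int) -> float:
    """Prior-adjusted posterior odds of model ``i`` over model ``j``."""
    return float(result.bayes_factors[i, j])
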