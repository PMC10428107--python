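"""MCMC convergence diagnostics: split-chain Gelman-Rubin upper confidence
bound and autocorrelation-based effective sample size.

The stopping rule of the sampler requires, for every monitored parameter,
ESS above a target (default 3000) and the *upper confidence bound* of the
potential scale reduction factor at or below a target (default 1.01).  The
upper bound (not just the point estimate) is what guards against premature
declarations of convergence.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import f as f_dist


def _split_chains(x: np.ndarray) -> np.ndarray:
    """Split each chain in half, doubling the chain count."""
    c, t = x.shape
    half = t // 2
    return np.concatenate([x[:, :half], x[:, t - half:]], axis=0)


def gelman_rubin_upper(chains, split: bool = True, confidence: float = 0.975) -> float:
    """Upper confidence bound of the potential scale reduction factor.

    ``chains`` is an (n_chains, n_draws) array.  Implements the classical
    between/within variance decomposition with the degrees-of-freedom
    correction and an F-quantile upper bound on the random part of R^2
    (the construction used by the standard ``gelman.diag`` diagnostic),
    applied to split chains by default.  Chains that are all constant (and
    equal) return 1 by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    if split:
        x = _split_chains(x)
        m, n = x.shape
    s2 = x.var(axis=1, ddof=1)            # within-chain variances
    xbar = x.mean(axis=1)                 # chain means
    w = s2.mean()
    b = n * xbar.var(ddof=1)              # between-chain variance * n
    if w == 0:
        return 1.0 if b == 0 else np.inf
    muhat = xbar.mean()
    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * b**2 / (m - 1)
    cov_s2_xbar2 = np.cov(s2, xbar**2, ddof=1)[0, 1]
    cov_s2_xbar = np.cov(s2, xbar, ddof=1)[0, 1]
    var_wb = (n / m) * (cov_s2_xbar2 - 2.0 * muhat * cov_s2_xbar)
    v = (n - 1) * w / n + (1.0 + 1.0 / m) * b / n
    var_v = ((n - 1) ** 2 * var_w + (1.0 + 1.0 / m) ** 2 * var_b
             + 2.0 * (n - 1) * (1.0 + 1.0 / m) * var_wb) / n**2
    if var_v <= 0:
        df_adj = 1.0
    else:
        df_v = 2.0 * v**2 / var_v
        df_adj = (df_v + 3.0) / (df_v + 1.0)
    b_df = m - 1
    w_df = 2.0 * w**2 / var_w if var_w > 0 else np.inf
    r2_fixed = (n - 1.0) / n
    r2_random = (1.0 + 1.0 / m) * b / (n * w)
    r2_upper = r2_fixed + f_dist.ppf(confidence, b_df, w_df) * r2_random
    return float(np.sqrt(df_adj * r2_upper))


def gelman_rubin_point(chains, split: bool = True) -> float:
    """Point estimate of the potential scale reduction factor (same scheme)."""
    x = np.asarray(chains, dtype=float)
    if split:
        x = _split_chains(x)
    m, n = x.shape
    w = x.var(axis=1, ddof=1).mean()
    b = n * x.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    v = (n - 1) * w / n + (1.0 + 1.0 / m) * b / n
    return float(np.sqrt(v / w))


def effective_sample_size(chains) -> float:
    """Autocorrelation-based effective sample size, summed across chains.

    A constant set of chains has no information about the stationary
    distribution's spread; 0 is returned by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 10:
        raise ValueError("need at least 10 draws per chain")
    if np.all(x == x.flat[0]):
        return 0.0
    import arviz as az  # deferred: slow import
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(np.asarray(az.ess(az.convert_to_dataset(x))["x"].values))
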