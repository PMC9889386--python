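"""Phylogenetic signal (Pagel's lambda) and simulation-based phylogenetic
ANOVA with Hommel-adjusted post-hoc comparisons.

For a continuous trait y on n tips, the lambda model is
y ~ MVN(mu 1, sigma2 * C(lambda)) where C(lambda) scales the off-diagonal
shared-path-length covariance by lambda.  lambda-hat maximizes the profile
likelihood over [0, 1] (GLS mean and variance profiled out); the reported
test is a likelihood ratio of lambda-hat against lambda = 0 on chi2(1).

For a discrete trait, lambda enters through the tree transform and is
maximized jointly with the CTMC rates of the pruning likelihood.

The phylogenetic ANOVA follows the simulation approach: the observed
one-way F statistic is referred to a null distribution of F values computed
from Brownian-motion datasets simulated on the tree (sigma2 estimated from
the data), keeping group labels fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from . import ctmc
from .treeio import PhyloTree, lambda_transform, phylo_covariance

__all__ = [
    "LambdaFit",
    "AnovaResult",
    "lambda_continuous",
    "lambda_discrete",
    "phylo_anova",
    "hommel_adjust",
]


@dataclass
class LambdaFit:
    lam: float
    loglik_lambda: float
    loglik_zero: float
    lr_pvalue: float
    kind: str
    flat_likelihood: bool = False
    sigma2: float = float("nan")
    mu: float = float("nan")


@dataclass
class AnovaResult:
    f_observed: float
    p_value: float
    group_means: pd.Series
    pairwise: pd.DataFrame     # pair, t, p_raw, p_hommel
    nsim: int
    seed: int


# ---- continuous lambda ---------------------------------------------------


def _gls_profile_loglik(y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of y ~ MVN(mu 1, s2 C) over (mu, s2)."""
    n = y.size
    L = np.linalg.cholesky(C)
    one = np.ones(n)
    z = scipy.linalg.solve_triangular(L, y, lower=True)
    u = scipy.linalg.solve_triangular(L, one, lower=True)
    mu = float(u @ z / (u @ u))
    r = z - mu * u
    s2 = float(r @ r / n)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return ll, mu, s2


import scipy.linalg  # noqa: E402  (used inside _gls_profile_loglik)


def lambda_continuous(tree: PhyloTree, y) -> LambdaFit:
    """Maximum-likelihood Pagel's lambda for a continuous trait."""
    if isinstance(y, pd.Series):
        y = y.loc[list(tree.tip_labels)].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != tree.n_tips:
        raise ValueError("y must align with tree tips")
    if n < 10:
        raise ValueError("need at least 10 tips")
    if np.allclose(y, y[0]):
        raise ValueError("constant trait: lambda undefined")
    C = phylo_covariance(tree)
    D = np.diag(np.diag(C))
    jitter = 1e-10 * np.trace(C) / n * np.eye(n)

    def nll(lam: float) -> float:
        V = lam * C + (1 - lam) * D + jitter
        try:
            return -_gls_profile_loglik(y, V)[0]
        except np.linalg.LinAlgError:
            return np.inf

    grid = np.linspace(0, 1, 11)
    vals = [nll(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = max(0.0, grid[i] - 0.1), min(1.0, grid[i] + 0.1)
    res = scipy.optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    lam = float(res.x)
    ll_lam = -float(res.fun)
    ll_zero = -vals[0]
    if ll_zero > ll_lam:      # optimum at the boundary lambda=0
        lam, ll_lam = 0.0, ll_zero
    lr = 2.0 * (ll_lam - ll_zero)
    p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=1))
    flat = bool(np.ptp(vals) < 1e-8)
    V = lam * C + (1 - lam) * D + jitter
    _, mu, s2 = _gls_profile_loglik(y, V)
    return LambdaFit(lam, ll_lam, ll_zero, p, "continuous", flat, s2, mu)


def lambda_discrete(tree: PhyloTree, trait, kind: str = "ER") -> LambdaFit:
    """Joint ML over lambda and CTMC rates on the lambda-transformed tree."""
    def fit_at(lam: float) -> float:
        t = lambda_transform(tree, lam)
        return ctmc.fit_ml_discrete(t, trait, kind, n_restarts=3).loglik

    grid = np.linspace(0, 1, 6)
    vals = [fit_at(g) for g in grid]
    i = int(np.argmax(vals))
    lo, hi = max(0.0, grid[i] - 0.2), min(1.0, grid[i] + 0.2)
    res = scipy.optimize.minimize_scalar(lambda l: -fit_at(l), bounds=(lo, hi),
                                         method="bounded",
                                         options={"xatol": 1e-3})
    lam = float(res.x)
    ll_lam = -float(res.fun)
    ll_zero = vals[0]
    # prefer the boundary when the profile is flat to numerical precision
    if ll_lam - ll_zero < 1e-3:
        lam, ll_lam = 0.0, ll_zero
    lr = 2.0 * (ll_lam - ll_zero)
    p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=1))
    flat = bool(max(vals) - min(vals) < 1e-8)
    return LambdaFit(lam, ll_lam, ll_zero, p, "discrete", flat)


# ---- phylogenetic ANOVA --------------------------------------------------


def _f_stats(Y: np.ndarray, groups: np.ndarray, k: int) -> np.ndarray:
    """One-way ANOVA F for each row of Y (vectorized over simulations)."""
    n = Y.shape[1]
    grand = Y.mean(axis=1, keepdims=True)
    ss_tot = ((Y - grand) ** 2).sum(axis=1)
    ss_b = np.zeros(Y.shape[0])
    for g in range(k):
        m = groups == g
        ng = m.sum()
        gm = Y[:, m].mean(axis=1)
        ss_b += ng * (gm - grand[:, 0]) ** 2
    ss_w = ss_tot - ss_b
    return (ss_b / (k - 1)) / np.maximum(ss_w / (n - k), 1e-300)


def _pairwise_t(Y: np.ndarray, groups: np.ndarray, pairs) -> np.ndarray:
    """Pooled-variance two-sample t for each group pair, rows of Y."""
    n = Y.shape[1]
    k = len(np.unique(groups))
    grand_ss_w = np.zeros(Y.shape[0])
    means = {}
    counts = {}
    for g in np.unique(groups):
        m = groups == g
        means[g] = Y[:, m].mean(axis=1)
        counts[g] = int(m.sum())
        grand_ss_w += ((Y[:, m] - means[g][:, None]) ** 2).sum(axis=1)
    mse = grand_ss_w / (n - k)
    out = np.empty((len(pairs), Y.shape[0]))
    for idx, (a, b) in enumerate(pairs):
        se = np.sqrt(mse * (1.0 / counts[a] + 1.0 / counts[b]))
        out[idx] = (means[a] - means[b]) / np.maximum(se, 1e-300)
    return out


def phylo_anova(tree: PhyloTree, y, groups, nsim: int = 1000,
                seed: int = 0) -> AnovaResult:
    """Simulation-based phylogenetic ANOVA with post-hoc pairwise tests.

    The null distribution of F comes from ``nsim`` Brownian-motion datasets
    simulated on the tree with sigma2 estimated from the observed data by
    phylogenetic ML; group labels stay fixed.  Pairwise t statistics are
    referred to their own simulated nulls (two-sided) and Hommel-adjusted.
    """
    import warnings

    order = list(tree.tip_labels)
    if isinstance(y, pd.Series):
        y = y.loc[order].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(groups, pd.Series):
        groups = groups.loc[order]
    groups = np.asarray(groups)
    labels, gidx = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(gidx)
    if (counts < 2).any():
        raise ValueError("singleton group: post-hoc tests undefined")
    if nsim < 100:
        warnings.warn("nsim < 100 gives a coarse null", stacklevel=2)

    fit = lambda_continuous(tree, pd.Series(y, index=order)) if not np.allclose(y, y[0]) else None
    C = phylo_covariance(tree)
    s2 = fit.sigma2 if fit is not None else 1.0
    # BM null: sigma2 from the phylogenetic ML fit of the observed data
    s2_bm = _gls_profile_loglik(np.asarray(y, dtype=float), C + 1e-10 * np.eye(len(y)))[2] \
        if not np.allclose(y, y[0]) else 1.0
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(C + 1e-10 * np.trace(C) / len(y) * np.eye(len(y)))
    sims = np.sqrt(s2_bm) * (rng.standard_normal((nsim, len(y))) @ L.T)

    f_obs = float(_f_stats(y[None, :], gidx, k)[0])
    f_null = _f_stats(sims, gidx, k)
    p = float((1 + (f_null >= f_obs).sum()) / (nsim + 1))

    pairs = [(a, b) for i, a in enumerate(range(k)) for b in range(i + 1, k)]
    t_obs = _pairwise_t(y[None, :], gidx, pairs)[:, 0]
    t_null = _pairwise_t(sims, gidx, pairs)
    p_raw = np.array([
        (1 + (np.abs(t_null[i]) >= abs(t_obs[i])).sum()) / (nsim + 1)
        for i in range(len(pairs))
    ])
    p_adj = hommel_adjust(p_raw)
    pw = pd.DataFrame({
        "group_a": [labels[a] for a, _ in pairs],
        "group_b": [labels[b] for _, b in pairs],
        "t": t_obs, "p_raw": p_raw, "p_hommel": p_adj,
    })
    gm = pd.Series({labels[g]: y[gidx == g].mean() for g in range(k)})
    return AnovaResult(f_obs, p, gm, pw, nsim, seed)


def hommel_adjust(p) -> np.ndarray:
    """Hommel (1988) closed-testing p-value adjustment."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="hommel")[1]
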