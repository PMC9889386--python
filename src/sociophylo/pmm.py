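"""Gibbs-sampled phylogenetic mixed model (animal model) for trait and
gene-expression regressions, with pMCMC summaries and the distribution-fit
cut-score significance rule.

Model: y = X beta + a + e, with a ~ N(0, s2_a * A) where A is the
phylogenetic correlation matrix (covariance scaled to unit diagonal so s2_a
is in trait-variance units), and e ~ N(0, s2_e * I).  beta carries a flat
prior; both variances carry inverse-gamma priors parameterized by a prior
covariance V and degree of belief nu as IG(nu/2, nu*V/2) — the weak
(V=1, nu=0.002) default.

Updates are fully conjugate.  The phylogenetic effect is sampled in the
eigenbasis of A, where its full conditional is diagonal, so one posterior
draw costs one matrix-vector product.

pMCMC for a coefficient is twice the smaller tail probability of its
posterior draws crossing zero, floored at 2/(retained draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .synthetic_data import ExpressionPanel
from .treeio import PhyloTree, phylo_covariance, prune_to

__all__ = [
    "PmmConfig",
    "PosteriorSummary",
    "CutScore",
    "fit_pmm",
    "run_gene_models",
    "fit_cut_score",
    "select_significant",
]


@dataclass
class PmmConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 20
    seed: int = 0
    chains: int = 2

    @classmethod
    def desk(cls, seed: int = 0) -> "PmmConfig":
        return cls(seed=seed)

    @classmethod
    def paper(cls, seed: int = 0) -> "PmmConfig":
        return cls(iterations=1_000_000, burn_in=100_000, thinning=500,
                   seed=seed)

    @classmethod
    def quick(cls, seed: int = 0) -> "PmmConfig":
        """Per-gene screening profile: 4000 iterations, 1000 burn-in."""
        return cls(iterations=4_000, burn_in=1_000, thinning=3, seed=seed,
                   chains=2)


@dataclass
class PosteriorSummary:
    coefficients: pd.DataFrame   # index=name: post_mean, post_sd, pMCMC, ess, rhat
    s2_phylo: float
    s2_resid: float
    s2_phylo_sd: float
    s2_resid_sd: float
    n_draws: int
    n_tips: int
    converged: bool
    rhat_max: float

    def __getitem__(self, name: str) -> pd.Series:
        return self.coefficients.loc[name]


@dataclass
class CutScore:
    family: str                  # "normal" | "logistic"
    params: tuple
    cut: float
    ks_normal: float
    ks_logistic: float
    aic_normal: float
    aic_logistic: float


def _design_matrix(X) -> tuple[np.ndarray, list[str]]:
    """Expand a DataFrame to a numeric design with treatment coding."""
    if X is None:
        return np.empty((0, 0)), []
    if isinstance(X, pd.DataFrame):
        Xd = pd.get_dummies(X, drop_first=True, dtype=float)
        return Xd.to_numpy(dtype=float), list(Xd.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _gibbs_chain(y, X, U, d, V_prior, nu, n_iter, burn_in, thinning, rng):
    """One Gibbs chain.  U, d: eigenvectors/values of the phylogenetic
    correlation matrix A.  Returns draws of (beta, s2_a, s2_e)."""
    n, p = X.shape
    yt = U.T @ y                  # response in the eigenbasis
    Xt = U.T @ X
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX + 1e-12 * np.eye(p))
    shape_a0 = nu / 2.0
    scale_a0 = nu * V_prior / 2.0

    beta = XtX_inv @ (X.T @ y)
    s2_a, s2_e = np.var(y) / 2 + 1e-6, np.var(y) / 2 + 1e-6
    gamma = np.zeros(n)           # phylogenetic effect in eigenbasis

    n_keep = (n_iter - burn_in) // thinning
    betas = np.empty((n_keep, p))
    vs = np.empty((n_keep, 2))
    kept = 0
    for it in range(n_iter):
        # gamma | rest : diagonal normal in eigenbasis
        resid_t = yt - Xt @ beta
        prec = 1.0 / s2_e + 1.0 / (s2_a * d)
        mean = (resid_t / s2_e) / prec
        gamma = mean + rng.standard_normal(n) / np.sqrt(prec)
        # beta | rest : flat prior, residual y - U gamma
        r = y - U @ gamma
        mu_b = XtX_inv @ (X.T @ r)
        beta = mu_b + np.linalg.cholesky(s2_e * XtX_inv) @ rng.standard_normal(p)
        # variances | rest
        ssa = float((gamma ** 2 / d).sum())
        s2_a = 1.0 / rng.gamma(shape_a0 + n / 2.0, 1.0 / (scale_a0 + ssa / 2.0))
        e = r - X @ beta
        sse = float(e @ e)
        s2_e = 1.0 / rng.gamma(shape_a0 + n / 2.0, 1.0 / (scale_a0 + sse / 2.0))
        if it >= burn_in and (it - burn_in) % thinning == 0 and kept < n_keep:
            betas[kept] = beta
            vs[kept] = (s2_a, s2_e)
            kept += 1
    return betas[:kept], vs[:kept]


def _pmcmc(draws: np.ndarray) -> float:
    n = draws.size
    tail = min((draws > 0).mean(), (draws < 0).mean())
    return float(max(2.0 * tail, 2.0 / n))


def _split_rhat(per_chain: list[np.ndarray]) -> float:
    halves = []
    for c in per_chain:
        h = len(c) // 2
        if h >= 2:
            halves.append(c[:h])
            halves.append(c[h: 2 * h])
    if len(halves) < 2:
        return float("nan")
    seqs = np.array(halves)
    w = seqs.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    n = seqs.shape[1]
    b = n * seqs.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def fit_pmm(tree: PhyloTree, y, X=None, priors: tuple[float, float] = (1.0, 0.002),
            config: PmmConfig | None = None,
            eig=None) -> PosteriorSummary:
    """Fit the phylogenetic mixed model by conjugate Gibbs sampling.

    Parameters
    ----------
    y : Series indexed by species, or array in tip order.
    X : DataFrame (categoricals expanded to treatment codes) or array;
        an intercept column is always prepended.
    priors : (V, nu) of the inverse-gamma variance priors.
    eig : optional precomputed (U, d) eigendecomposition of the phylogenetic
        correlation matrix, to amortize across genes.
    """
    config = config or PmmConfig.desk()
    order = list(tree.tip_labels)
    if isinstance(y, pd.Series):
        y = y.loc[order].to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != tree.n_tips:
        raise ValueError("response must align with tree tips")
    if np.isnan(y).any():
        raise ValueError("response must be complete on modeled tips")
    if isinstance(X, pd.DataFrame):
        X = X.loc[order]
    Xm, names = _design_matrix(X)
    if Xm.size == 0:
        Xm = np.ones((n, 1))
        names = ["(Intercept)"]
    else:
        Xm = np.column_stack([np.ones(n), Xm])
        names = ["(Intercept)"] + names
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # identify aliased columns by pivoted QR
        _, _, piv = scipy.linalg.qr(Xm, pivoting=True)
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    if eig is None:
        A = phylo_covariance(tree, as_correlation=True)
        d, U = np.linalg.eigh(A)
        d = np.clip(d, 1e-8, None)
    else:
        U, d = eig
    V_prior, nu = priors
    per_chain_b, per_chain_v = [], []
    for c in range(config.chains):
        rng = np.random.default_rng(config.seed + 1000 * c)
        b, v = _gibbs_chain(y, Xm, U, d, V_prior, nu, config.iterations,
                            config.burn_in, config.thinning, rng)
        per_chain_b.append(b)
        per_chain_v.append(v)
    B = np.vstack(per_chain_b)
    V = np.vstack(per_chain_v)

    from .bayes_engine import _ess_ips

    rows = []
    rhat_max = 0.0
    for j, name in enumerate(names):
        draws = B[:, j]
        rhat = _split_rhat([b[:, j] for b in per_chain_b])
        rhat_max = max(rhat_max, rhat if np.isfinite(rhat) else 0.0)
        rows.append(dict(name=name, post_mean=draws.mean(),
                         post_sd=draws.std(ddof=1), pMCMC=_pmcmc(draws),
                         ess=_ess_ips(draws), rhat=rhat))
    coef = pd.DataFrame(rows).set_index("name")
    converged = bool(rhat_max < 1.1) if np.isfinite(rhat_max) else True
    return PosteriorSummary(
        coefficients=coef,
        s2_phylo=float(V[:, 0].mean()), s2_resid=float(V[:, 1].mean()),
        s2_phylo_sd=float(V[:, 0].std(ddof=1)),
        s2_resid_sd=float(V[:, 1].std(ddof=1)),
        n_draws=B.shape[0], n_tips=n, converged=converged,
        rhat_max=float(rhat_max),
    )


def run_gene_models(tree: PhyloTree, panel: ExpressionPanel,
                    traits: pd.DataFrame, schemes=("solitary", "pair-living",
                                                   "group-living", "three-state"),
                    covariates=("body_mass", "lifespan"),
                    config: PmmConfig | None = None,
                    priors: tuple[float, float] = (1.0, 0.002),
                    min_species: int = 10) -> pd.DataFrame:
    """Fit the per-gene phylogenetic mixed models.

    For every gene and every social-coding scheme, regresses that gene's
    expression on the social coding plus covariates.  Genes missing in a
    species use the tree pruned to their observed species.  Returns a long
    table (gene, model, coefficient, post_mean, post_sd, pMCMC, ess, rhat,
    n_species), with skipped genes listed under coefficient="(skipped)".
    """
    config = config or PmmConfig.quick()
    order = [s for s in tree.tip_labels if s in panel.values.index]
    if set(panel.values.index) - set(tree.tip_labels):
        raise ValueError("panel species must be a subset of tree tips")
    base = traits.loc[order].copy()
    # cache: observed-species tuple -> (modeling order, U, d)
    eig_cache: dict[tuple, tuple] = {}
    full_tree = prune_to(tree, order) if len(order) < tree.n_tips else tree
    A = phylo_covariance(full_tree, as_correlation=True)
    d, U = np.linalg.eigh(A)
    eig_cache[tuple(order)] = (list(full_tree.tip_labels), U,
                               np.clip(d, 1e-8, None))

    rows = []
    for gi, gene in enumerate(panel.genes):
        obs = [s for s in order if not panel.mask.loc[s, gene]]
        if len(obs) < min_species:
            rows.append(dict(gene=gene, model="-", coefficient="(skipped)",
                             post_mean=np.nan, post_sd=np.nan, pMCMC=np.nan,
                             ess=np.nan, rhat=np.nan, n_species=len(obs)))
            continue
        key = tuple(obs)
        if key not in eig_cache:
            sub = prune_to(tree, obs)
            Asub = phylo_covariance(sub, as_correlation=True)
            ds, Us = np.linalg.eigh(Asub)
            eig_cache[key] = (list(sub.tip_labels), Us, np.clip(ds, 1e-8, None))
        subtree_order, U_g, d_g = eig_cache[key]
        y = panel.values.loc[subtree_order, gene]
        for scheme in schemes:
            X = _scheme_design(base.loc[subtree_order], scheme, covariates)
            cfg = PmmConfig(config.iterations, config.burn_in, config.thinning,
                            seed=config.seed + 13 * gi, chains=config.chains)
            try:
                fake = _TipView(subtree_order)
                summ = fit_pmm(fake, y, X, priors, cfg, eig=(U_g, d_g))
            except ValueError:
                rows.append(dict(gene=gene, model=scheme,
                                 coefficient="(failed)", post_mean=np.nan,
                                 post_sd=np.nan, pMCMC=np.nan, ess=np.nan,
                                 rhat=np.nan, n_species=len(subtree_order)))
                continue
            for cname, crow in summ.coefficients.iterrows():
                rows.append(dict(gene=gene, model=scheme, coefficient=cname,
                                 post_mean=crow.post_mean, post_sd=crow.post_sd,
                                 pMCMC=crow.pMCMC, ess=crow.ess,
                                 rhat=crow.rhat, n_species=len(subtree_order)))
    return pd.DataFrame(rows)


class _TipView:
    """Minimal tree stand-in carrying only a tip ordering, for fits that
    supply a precomputed eigendecomposition."""

    def __init__(self, labels):
        self.tip_labels = list(labels)
        self.n_tips = len(self.tip_labels)


def _scheme_design(tr: pd.DataFrame, scheme: str, covariates) -> pd.DataFrame:
    from .traits import encode_social

    cols = {}
    t = tr.copy()
    if "species" not in t.columns:
        t = t.assign(species=t.index)
    if scheme == "three-state":
        coded = encode_social(t, "three-state")
        # ambiguity sets cannot enter a regression design; use the species'
        # first listed state for polymorphic species
        lab = coded.map(lambda s: sorted(s)[0] if len(s) > 1 else next(iter(s)))
        cols["social"] = pd.Categorical(lab.values)
    else:
        scheme_map = {"solitary": "solitary-vs-rest",
                      "pair-living": "pair-vs-rest",
                      "group-living": "group-vs-rest"}
        coded = encode_social(t, scheme_map[scheme])
        cols[scheme] = coded.map(
            lambda v: v if np.isscalar(v) and not isinstance(v, frozenset)
            else 1).astype(float).values
    X = pd.DataFrame(cols, index=tr.index)
    for cov in covariates:
        if cov in tr.columns:
            col = tr[cov]
            if col.dtype.kind in "fiu":
                X[cov] = np.log10(col) if (col > 0).all() and col.max() > 100 \
                    else col
            else:
                X[cov] = pd.Categorical(col)
    return X


# ---- cut score -----------------------------------------------------------


def fit_cut_score(post_means) -> CutScore:
    """Distribution-fit significance threshold for posterior means.

    Fits normal and logistic families by maximum likelihood, chooses the
    better Kolmogorov-Smirnov fit (ties broken by AIC), and returns the
    fitted upper 0.975 quantile as the cut value (two-tailed 0.05 rule).
    """
    x = np.asarray(post_means, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 100:
        raise ValueError("need at least 100 posterior means")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) posterior means")
    mu_n, sd_n = scipy.stats.norm.fit(x)
    loc_l, s_l = scipy.stats.logistic.fit(x)
    ks_n = scipy.stats.kstest(x, "norm", args=(mu_n, sd_n)).statistic
    ks_l = scipy.stats.kstest(x, "logistic", args=(loc_l, s_l)).statistic
    ll_n = scipy.stats.norm.logpdf(x, mu_n, sd_n).sum()
    ll_l = scipy.stats.logistic.logpdf(x, loc_l, s_l).sum()
    aic_n, aic_l = 4 - 2 * ll_n, 4 - 2 * ll_l
    if not np.isclose(ks_n, ks_l):
        family = "normal" if ks_n < ks_l else "logistic"
    else:
        family = "normal" if aic_n <= aic_l else "logistic"
    if family == "normal":
        cut = float(scipy.stats.norm.ppf(0.975, mu_n, sd_n))
        params = (float(mu_n), float(sd_n))
    else:
        cut = float(scipy.stats.logistic.ppf(0.975, loc_l, s_l))
        params = (float(loc_l), float(s_l))
    return CutScore(family, params, cut, float(ks_n), float(ks_l),
                    float(aic_n), float(aic_l))


def select_significant(results: pd.DataFrame, cut: CutScore | float,
                       coefficient: str | None = None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Apply the joint significance rule: pMCMC < alpha and |post mean| >
    cut.  Adds a ``direction`` column (up/down by the sign of post mean)."""
    cut_val = cut.cut if isinstance(cut, CutScore) else float(cut)
    df = results.copy()
    if coefficient is not None:
        df = df[df["coefficient"] == coefficient]
    sig = df[(df["pMCMC"] < alpha) & (df["post_mean"].abs() > cut_val)].copy()
    sig["direction"] = np.where(sig["post_mean"] > 0, "up", "down")
    return sig
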