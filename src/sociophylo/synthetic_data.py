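"""Synthetic data with known ground truth for every downstream stage.

Generators cover pure-birth (Yule) trees, discrete traits evolved by exact
event-driven (Gillespie) simulation under arbitrary rate matrices, correlated
binary trait pairs under dependent/independent joint models, Brownian-motion
continuous traits with Pagel's lambda, per-gene expression panels with a
phylogenetic random effect and planted fixed effects, negative-binomial count
matrices, gene sets with planted score enrichment, and the three missingness
patterns (MCAR, mass-dependent MAR, clade-concentrated MAR) used by the
imputation benchmark.

Every generator takes an explicit seed and returns a
:class:`SimulationTruth` describing exactly what was planted, so downstream
recovery can be scored without re-reading generator code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctmc import RateModel
from .treeio import PhyloTree, phylo_covariance, lambda_transform

__all__ = [
    "SimulationTruth",
    "ExpressionPanel",
    "simulate_yule_tree",
    "simulate_discrete_trait",
    "simulate_binary_pair",
    "simulate_continuous_bm",
    "simulate_expression_panel",
    "simulate_count_matrix",
    "make_gene_sets",
    "inject_missingness",
]


@dataclass
class SimulationTruth:
    """Record of the generator, seed, and planted parameters of an artifact."""

    generator: str
    seed: int
    parameters: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"generator: {self.generator}", f"seed: {self.seed}"]
        for key, val in self.parameters.items():
            lines.append(f"{key}: {val}")
        return "\n".join(lines) + "\n"


@dataclass
class ExpressionPanel:
    """Species x gene log-expression matrix with companion truth.

    ``values`` rows are tree tips (index = species names); ``mask`` marks
    entries treated as missing (gene not detected in that species).
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    traits: pd.DataFrame
    truth: SimulationTruth

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


# ---- trees ---------------------------------------------------------------


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0) -> PhyloTree:
    """Pure-birth tree with exactly ``n_tips`` extant tips.

    Standard constant-rate Yule process: with n lineages the waiting time to
    the next split is Exponential(n * birth_rate); the splitting lineage is
    uniform. Pendant edges are extended to the final time, so the tree is
    ultrametric by construction.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    start = np.zeros(n_nodes)   # time each lineage (edge above the node) began
    end = np.zeros(n_nodes)
    next_internal = n_tips      # internal ids n_tips..n_nodes-1
    root = next_internal
    next_internal += 1
    t = 0.0
    # the root lineage splits at time 0: the rooted tree of the extant clade
    # active lineages are (parent id, start time) pairs awaiting their node id
    pending: list[tuple[int, float]] = [(root, 0.0), (root, 0.0)]
    active = [0, 1]
    tip_ptr = 0
    n_active = 2
    while n_active < n_tips:
        t += rng.exponential(1.0 / (birth_rate * n_active))
        pick = int(rng.integers(n_active))
        pid = active.pop(pick)
        par, t0 = pending[pid]
        node = next_internal
        next_internal += 1
        parent[node] = par
        start[node], end[node] = t0, t
        for _ in range(2):
            active.append(len(pending))
            pending.append((node, t))
        n_active += 1
    # one extra waiting time to set the present (depth of the tree)
    t += rng.exponential(1.0 / (birth_rate * n_active))
    for pid in active:
        par, t0 = pending[pid]
        node = tip_ptr
        tip_ptr += 1
        parent[node] = par
        start[node], end[node] = t0, t
    blen = end - start
    blen[root] = 0.0
    labels = [f"sp{i:04d}" for i in range(n_tips)]
    # randomize tip label placement so labels are exchangeable
    perm = rng.permutation(n_tips)
    order = np.argsort(perm)
    new_parent = parent.copy()
    new_blen = blen.copy()
    new_parent[:n_tips] = parent[:n_tips][order]
    new_blen[:n_tips] = blen[:n_tips][order]
    return PhyloTree(new_parent, new_blen, labels)


# ---- discrete traits -----------------------------------------------------


def _gillespie_branch(state: int, Q: np.ndarray, t: float,
                      rng: np.random.Generator) -> int:
    """Exact event-driven CTMC simulation along one branch."""
    k = Q.shape[0]
    elapsed = 0.0
    while True:
        out = -Q[state, state]
        if out <= 0:
            return state
        elapsed += rng.exponential(1.0 / out)
        if elapsed >= t:
            return state
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(k, p=probs))


def simulate_discrete_trait(tree: PhyloTree, model: RateModel,
                            root_distribution=None, seed: int = 0
                            ) -> tuple[pd.Series, SimulationTruth]:
    """One discrete state per tip, simulated exactly along each branch."""
    Q = model.q_matrix()
    k = Q.shape[0]
    if root_distribution is None:
        root_distribution = model.root_distribution()
    root_distribution = np.asarray(root_distribution, dtype=float)
    if root_distribution.size != k or not np.isclose(root_distribution.sum(), 1.0) \
            or (root_distribution < 0).any():
        raise ValueError("root_distribution must be a probability vector over states")
    rng = np.random.default_rng(seed)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    order = tree.postorder()[::-1]   # preorder: parents before children
    for node in order:
        p = tree.parent[node]
        if p < 0:
            states[node] = rng.choice(k, p=root_distribution)
        else:
            states[node] = _gillespie_branch(states[p], Q, tree.blen[node], rng)
    col = pd.Series(states[: tree.n_tips], index=tree.tip_labels, name="state")
    truth = SimulationTruth("discrete_trait", seed, {
        "Q": Q.tolist(), "root_distribution": root_distribution.tolist(),
    })
    return col, truth


def simulate_binary_pair(tree: PhyloTree, pair_model: RateModel, seed: int = 0
                         ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Two binary traits evolved jointly under a 4-state model.

    Joint states are ordered ((0,0),(0,1),(1,0),(1,1)); dual transitions
    (both traits flipping at once) must have rate exactly 0.
    """
    Q = pair_model.q_matrix()
    if Q.shape[0] != 4:
        raise ValueError("pair model must have 4 joint states")
    dual = [(0, 3), (3, 0), (1, 2), (2, 1)]
    if any(Q[i, j] != 0 for i, j in dual):
        raise ValueError("dual transitions must have rate 0")
    joint, truth = simulate_discrete_trait(tree, pair_model, seed=seed)
    x = (joint.values >= 2).astype(int)   # first trait = high bit
    y = (joint.values % 2).astype(int)
    df = pd.DataFrame({"x": x, "y": y}, index=tree.tip_labels)
    kind = "dependent" if _is_dependent(Q) else "independent"
    truth = SimulationTruth("binary_pair", seed,
                            {"Q": Q.tolist(), "kind": kind})
    return df, truth


def _is_dependent(Q: np.ndarray) -> bool:
    # independent iff each trait's transition rate ignores the other's state
    checks = [
        (Q[0, 2], Q[1, 3]),   # x: 0->1 given y=0 vs y=1
        (Q[2, 0], Q[3, 1]),   # x: 1->0
        (Q[0, 1], Q[2, 3]),   # y: 0->1 given x=0 vs x=1
        (Q[1, 0], Q[3, 2]),   # y: 1->0
    ]
    return any(not np.isclose(a, b) for a, b in checks)


# ---- continuous traits ---------------------------------------------------


def simulate_continuous_bm(tree: PhyloTree, sigma2: float = 1.0,
                           lam: float = 1.0, mean: float = 0.0,
                           seed: int = 0, size: int = 1
                           ) -> tuple[pd.DataFrame, SimulationTruth]:
    """Brownian-motion tip values with Pagel's lambda signal strength.

    Tip values are multivariate normal with covariance sigma2 * C(lambda),
    where C(lambda) is the shared-path-length matrix with off-diagonals
    scaled by lambda.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    rng = np.random.default_rng(seed)
    C = phylo_covariance(lambda_transform(tree, lam))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    z = rng.standard_normal((size, tree.n_tips))
    vals = mean + np.sqrt(sigma2) * (z @ L.T)
    df = pd.DataFrame(vals.T, index=tree.tip_labels,
                      columns=[f"rep{i}" for i in range(size)])
    truth = SimulationTruth("continuous_bm", seed, {
        "sigma2": sigma2, "lambda": lam, "mean": mean})
    return df, truth


# ---- expression panel ----------------------------------------------------


def simulate_expression_panel(tree: PhyloTree, traits: pd.DataFrame,
                              n_genes: int,
                              effect_spec: dict | None = None,
                              variances: tuple[float, float] = (1.0, 1.0),
                              missing_fraction: float = 0.0,
                              seed: int = 0) -> ExpressionPanel:
    """Per-gene log-expression with phylogenetic random effect and planted
    fixed effects.

    effect_spec maps a predictor column of ``traits`` to
    (fraction_of_true_genes, effect_size).  For each gene g:
    y_g = X beta_g + a_g + e_g with a_g ~ N(0, s2_phylo * A) (A the
    phylogenetic correlation matrix) and e_g ~ N(0, s2_resid * I).
    """
    effect_spec = effect_spec or {}
    s2_phylo, s2_resid = variances
    if s2_phylo < 0 or s2_resid <= 0:
        raise ValueError("variances must be positive (phylogenetic may be 0)")
    for pred, (frac, _) in effect_spec.items():
        if pred not in traits.columns:
            raise ValueError(f"predictor {pred!r} not in traits")
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    A = phylo_covariance(tree, as_correlation=True)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    order = list(tree.tip_labels)
    traits = traits.loc[order]

    genes = [f"g{i:05d}" for i in range(n_genes)]
    betas = {pred: np.zeros(n_genes) for pred in effect_spec}
    planted: dict[str, list[str]] = {}
    for pred, (frac, size) in effect_spec.items():
        n_true = int(round(frac * n_genes))
        chosen = rng.choice(n_genes, size=n_true, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_true)
        betas[pred][chosen] = size * signs
        planted[pred] = [genes[i] for i in chosen]

    Y = np.zeros((n, n_genes))
    for pred in effect_spec:
        x = np.asarray(traits[pred], dtype=float)
        Y += np.outer(x, betas[pred])
    if s2_phylo > 0:
        Y += np.sqrt(s2_phylo) * (L @ rng.standard_normal((n, n_genes)))
    Y += np.sqrt(s2_resid) * rng.standard_normal((n, n_genes))

    mask = np.zeros((n, n_genes), dtype=bool)
    if missing_fraction > 0:
        n_miss = int(round(missing_fraction * n))
        for g in range(n_genes):
            miss = rng.choice(n, size=rng.integers(0, n_miss + 1), replace=False)
            mask[miss, g] = True

    values = pd.DataFrame(Y, index=order, columns=genes)
    mask_df = pd.DataFrame(mask, index=order, columns=genes)
    truth = SimulationTruth("expression_panel", seed, {
        "betas": {p: b.tolist() for p, b in betas.items()},
        "planted": planted,
        "s2_phylo": s2_phylo, "s2_resid": s2_resid,
        "genes": genes,
    })
    return ExpressionPanel(values, mask_df, traits, truth)


# ---- counts --------------------------------------------------------------


def simulate_count_matrix(n_genes: int, n_samples: int,
                          library_sizes=None, dispersion: float = 0.1,
                          seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Negative-binomial count matrix with log-normal gene abundances.

    Expected column sums approximate ``library_sizes``; gene lengths are
    sampled uniformly in [200, 10000] bases (assembly minimum contig 200 bp).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if library_sizes is None:
        library_sizes = np.full(n_samples, 1_000_000)
    library_sizes = np.asarray(library_sizes)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    rel = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    rel /= rel.sum()
    mu = np.outer(rel, library_sizes)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    lengths = rng.integers(200, 10001, size=n_genes)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cols = [f"s{j:02d}" for j in range(n_samples)]
    cm = pd.DataFrame(counts, index=genes, columns=cols)
    gl = pd.Series(lengths, index=genes, name="length")
    truth = SimulationTruth("count_matrix", seed, {
        "library_sizes": library_sizes.tolist(), "dispersion": dispersion})
    return cm, gl, truth


# ---- gene sets -----------------------------------------------------------


def make_gene_sets(n_background_genes: int, n_sets: int,
                   size_range: tuple[int, int] = (10, 100),
                   planted=None, seed: int = 0):
    """Random gene sets over a background with optional planted score shifts.

    Background gene scores are standard normal; a planted entry
    (set_id, shift) adds ``shift`` (in score SD units) to every member of
    that set.  Returns (sets dict, scores Series, truth).
    """
    lo, hi = size_range
    if lo < 2:
        raise ValueError("minimum set size must be >= 2")
    if hi > n_background_genes:
        raise ValueError("set sizes cannot exceed the background")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_background_genes)]
    scores = pd.Series(rng.standard_normal(n_background_genes), index=genes,
                       name="score")
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_background_genes, size=size, replace=False)
        sets[f"set{s:04d}"] = [genes[i] for i in members]
    planted = list(planted or [])
    for set_id, shift in planted:
        if set_id not in sets:
            raise KeyError(set_id)
        scores.loc[sets[set_id]] += shift
    truth = SimulationTruth("gene_sets", seed, {
        "planted": [(sid, float(sh)) for sid, sh in planted],
        "n_sets": n_sets, "size_range": list(size_range)})
    return sets, scores, truth


# ---- missingness ---------------------------------------------------------


def inject_missingness(table: pd.DataFrame, column: str, pattern: str,
                       fraction: float, seed: int = 0,
                       tree: PhyloTree | None = None
                       ) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Mask exactly round(fraction * n) entries of a complete column.

    Patterns: MCAR (uniform), MAR-BM (logistic masking probability in body
    mass rank), MAR-Phy (masking concentrated in randomly chosen clades;
    requires the tree).  Returns (masked table, true values of the masked
    entries, truth record).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if column not in table.columns:
        raise KeyError(column)
    if table[column].isna().any():
        raise ValueError(f"column {column!r} must be complete")
    rng = np.random.default_rng(seed)
    n = len(table)
    n_mask = int(round(fraction * n))
    n_mask = max(1, min(n - 1, n_mask))

    if pattern == "MCAR":
        idx = rng.choice(n, size=n_mask, replace=False)
    elif pattern == "MAR-BM":
        if "body_mass" not in table.columns:
            raise ValueError("MAR-BM requires a body_mass column")
        ranks = table["body_mass"].rank().to_numpy()
        z = (ranks - ranks.mean()) / ranks.std()
        logits = 2.0 * z      # slope fixed; intercept irrelevant after top-k
        p = 1.0 / (1.0 + np.exp(-logits))
        keys = rng.uniform(size=n) ** (1.0 / np.maximum(p, 1e-12))
        idx = np.argsort(-keys)[:n_mask]      # weighted sampling w/o replacement
    elif pattern == "MAR-Phy":
        if tree is None:
            raise ValueError("MAR-Phy requires the tree")
        order = {name: i for i, name in enumerate(tree.tip_labels)}
        ch = tree.children()
        # pick random internal clades until their union covers >= n_mask tips
        internals = [x for x in range(tree.n_tips, tree.n_nodes)]
        chosen: set[int] = set()
        rng.shuffle(internals)
        species = list(table.index if "species" not in table.columns
                       else table["species"])
        for node in internals:
            stack, tips = [node], []
            while stack:
                u = stack.pop()
                if u < tree.n_tips:
                    tips.append(u)
                else:
                    stack.extend(ch[u])
            if len(tips) > max(3, n_mask // 2):
                continue
            chosen.update(tips)
            if len(chosen) >= n_mask:
                break
        pool = [i for i, sp in enumerate(species) if order.get(sp, -1) in chosen]
        if len(pool) >= n_mask:
            idx = rng.choice(pool, size=n_mask, replace=False)
        else:   # pad with random rows to hit the exact count
            rest = [i for i in range(n) if i not in pool]
            extra = rng.choice(rest, size=n_mask - len(pool), replace=False)
            idx = np.concatenate([pool, extra]).astype(int)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    out = table.copy()
    truth_vals = out[column].iloc[idx].copy()
    col_loc = out.columns.get_loc(column)
    out.iloc[idx, col_loc] = np.nan
    truth = SimulationTruth("missingness", seed, {
        "pattern": pattern, "fraction": fraction, "column": column,
        "n_masked": int(n_mask)})
    return out, truth_vals, truth
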