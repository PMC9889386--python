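"""Discrete-trait continuous-time Markov chain machinery.

Rate-matrix construction (equal-rates, increasing-complexity, all-rates-
different and custom partitions), the Felsenstein pruning likelihood with
ambiguous tip states, and maximum-likelihood rate estimation.

The pruning implementation is array-based and level-batched: per-branch
transition matrices exp(Q t) come from one eigendecomposition of Q broadcast
over all branch lengths, and conditional tip-likelihood vectors are combined
in vectorized sweeps over tree levels.  This makes the likelihood cheap
enough to sit inside MCMC and stepping-stone loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

from .treeio import PhyloTree

__all__ = [
    "RateModel",
    "FitResult",
    "build_rate_matrix",
    "pruning_loglik",
    "fit_ml_discrete",
    "tip_partials",
    "transition_matrices",
]

ZERO = "zero"


@dataclass
class RateModel:
    """Parameterized CTMC over an ordered state space.

    ``partition`` maps ordered state-index pairs (i, j), i != j, to a rate
    class id or the literal string "zero"; ``rates`` maps class ids to
    non-negative values.  Diagonals are implied (rows sum to zero).
    """

    states: tuple
    partition: dict
    rates: dict
    root_rule: str | np.ndarray = "uniform"

    @property
    def k(self) -> int:
        return len(self.states)

    @property
    def n_free(self) -> int:
        return len(set(self.partition.values()) - {ZERO})

    def class_ids(self) -> list:
        seen = []
        for v in self.partition.values():
            if v != ZERO and v not in seen:
                seen.append(v)
        return seen

    def q_matrix(self) -> np.ndarray:
        k = self.k
        Q = np.zeros((k, k))
        for (i, j), cls in self.partition.items():
            Q[i, j] = 0.0 if cls == ZERO else self.rates[cls]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def with_rates(self, values: np.ndarray) -> "RateModel":
        ids = self.class_ids()
        return RateModel(self.states, dict(self.partition),
                         dict(zip(ids, values)), self.root_rule)

    def root_distribution(self) -> np.ndarray:
        if isinstance(self.root_rule, str):
            if self.root_rule == "uniform":
                return np.full(self.k, 1.0 / self.k)
            if self.root_rule == "stationary":
                return stationary_distribution(self.q_matrix())
            raise ValueError(f"unknown root rule {self.root_rule!r}")
        v = np.asarray(self.root_rule, dtype=float)
        if v.size != self.k or not np.isclose(v.sum(), 1.0) or (v < 0).any():
            raise ValueError("root distribution must be a probability vector")
        return v


@dataclass
class FitResult:
    model: RateModel
    rates: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    boundary: bool = False
    n_free: int = 0
    message: str = ""


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def build_rate_matrix(kind: str, states, rates, zero_pairs=None,
                      root_rule="uniform", partition_arg=None) -> RateModel:
    """Construct a RateModel of a named kind.

    kind:
      - "ER": one shared rate on every off-diagonal.
      - "IC": 3 social states only; transitions solitary<->group-living are
        forbidden (rate exactly 0), the remaining 4 positions free.
      - "ARD": k(k-1) free rates, row-major order of off-diagonal positions.
      - "custom": caller supplies a partition via ``rates`` (dict of class
        id -> value) and ``zero_pairs``.
    """
    states = tuple(states)
    k = len(states)
    rates = np.atleast_1d(np.asarray(rates, dtype=float)) if not isinstance(rates, dict) else rates
    if not isinstance(rates, dict) and (rates < 0).any():
        raise ValueError("rates must be non-negative")
    pairs = [(i, j) for i in range(k) for j in range(k) if i != j]

    if kind == "ER":
        partition = {p: "q" for p in pairs}
        ratemap = {"q": float(np.ravel(rates)[0])}
    elif kind == "IC":
        if k != 3:
            raise ValueError("IC model is defined for the 3 social states only")
        # forbidden: direct solitary <-> group-living (state indices 0 and 2
        # under the canonical ordering solitary, pair-living, group-living)
        partition = {}
        free = [p for p in pairs if set(p) != {0, 2}]
        vals = np.ravel(rates)
        if vals.size not in (1, len(free)):
            raise ValueError(f"IC expects 1 or {len(free)} rates")
        if vals.size == 1:
            vals = np.repeat(vals, len(free))
        ratemap = {}
        for idx, p in enumerate(free):
            partition[p] = f"q{p[0]}{p[1]}"
            ratemap[f"q{p[0]}{p[1]}"] = float(vals[idx])
        for p in pairs:
            if set(p) == {0, 2}:
                partition[p] = ZERO
    elif kind == "ARD":
        vals = np.ravel(rates)
        if vals.size == 1:
            vals = np.repeat(vals, len(pairs))
        if vals.size != len(pairs):
            raise ValueError(f"ARD expects {len(pairs)} rates")
        partition = {p: f"q{p[0]}{p[1]}" for p in pairs}
        ratemap = {f"q{p[0]}{p[1]}": float(v) for p, v in zip(pairs, vals)}
    elif kind == "custom":
        if not isinstance(rates, dict):
            raise ValueError("custom kind takes rates as a dict class->value")
        if partition_arg is None:
            # single shared class on all positions except explicit zeros
            zero_pairs = set(tuple(p) for p in (zero_pairs or []))
            cls_id = next(iter(rates))
            partition = {p: (ZERO if p in zero_pairs else cls_id) for p in pairs}
        else:
            partition = {tuple(p): c for p, c in partition_arg.items()}
            missing = set(pairs) - set(partition)
            if missing:
                raise ValueError(f"partition misses positions {sorted(missing)}")
        ratemap = {c: float(v) for c, v in rates.items()}
        if any(v < 0 for v in ratemap.values()):
            raise ValueError("rates must be non-negative")
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return RateModel(states, partition, ratemap, root_rule)


# ---- likelihood ----------------------------------------------------------


def tip_partials(tree: PhyloTree, trait, k: int) -> np.ndarray:
    """Indicator partial-likelihood vectors over the ambiguity set of each tip.

    ``trait`` maps species name -> state index, set of state indices, or an
    explicit length-k vector.  Missing species raise KeyError.
    """
    import pandas as pd

    if isinstance(trait, pd.Series):
        trait = trait.to_dict()
    part = np.zeros((tree.n_tips, k))
    for i, name in enumerate(tree.tip_labels):
        if name not in trait:
            raise KeyError(f"tip {name!r} absent from trait data")
        v = trait[name]
        if np.isscalar(v) and not isinstance(v, (set, frozenset)):
            part[i, int(v)] = 1.0
        elif isinstance(v, (set, frozenset, list, tuple)) and len(v) <= k:
            for s in v:
                part[i, int(s)] = 1.0
        else:
            part[i] = np.asarray(v, dtype=float)
        if part[i].sum() == 0:
            raise ValueError(f"tip {name!r} has empty state set")
    return part


def transition_matrices(Q: np.ndarray, t: np.ndarray) -> np.ndarray:
    """exp(Q t) for a vector of branch lengths t, shape (len(t), k, k).

    Eigendecomposition of Q broadcast over t; falls back to scipy's expm per
    unique length when the eigensystem is ill-conditioned.
    """
    t = np.asarray(t, dtype=float)
    k = Q.shape[0]
    ok = False
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        # cheap conditioning check: eigenbasis must reconstruct the identity
        ok = bool(np.abs(V @ Vinv - np.eye(k)).max() < 1e-9)
    except np.linalg.LinAlgError:
        ok = False
    if ok:
        if _HAVE_NUMBA:
            M = np.einsum("il,lj->lij", V.astype(complex),
                          Vinv.astype(complex))
            return _propagator_kernel(t, w.astype(complex), M)
        E = np.exp(np.outer(t, w))
        P = np.einsum("ij,ej,jk->eik", V, E, Vinv)
        P = np.real(P)
    else:
        P = np.empty((t.size, k, k))
        uniq, inv = np.unique(t, return_inverse=True)
        mats = np.array([scipy.linalg.expm(Q * u) for u in uniq])
        P = mats[inv]
    np.clip(P, 0.0, None, out=P)
    # renormalize tiny numerical drift; rows of exp(Qt) sum to 1
    P /= P.sum(axis=2, keepdims=True)
    return P


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:                                   # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@_njit(cache=True)
def _propagator_kernel(t, w, M):
    """P(t_e) = Re sum_l exp(w_l t_e) M_l with clipping and row renorm."""
    ne = t.shape[0]
    k = w.shape[0]
    P = np.empty((ne, k, k))
    for e in range(ne):
        for i in range(k):
            for j in range(k):
                P[e, i, j] = 0.0
        for l in range(k):
            f = np.exp(w[l] * t[e])
            for i in range(k):
                for j in range(k):
                    P[e, i, j] += (f * M[l, i, j]).real
        for i in range(k):
            rs = 0.0
            for j in range(k):
                if P[e, i, j] < 0.0:
                    P[e, i, j] = 0.0
                rs += P[e, i, j]
            if rs > 0.0:
                for j in range(k):
                    P[e, i, j] /= rs
    return P


@_njit(cache=True)
def _prune_kernel(order, child_flat, child_off, n_tips, P, partial, root_dist):
    """Sequential postorder pruning with per-node rescaling.

    ``partial`` arrives with tip rows filled; internal rows are overwritten.
    Returns the log-likelihood.
    """
    k = P.shape[1]
    logsc = 0.0
    for oi in range(order.shape[0]):
        node = order[oi]
        if node < n_tips:
            continue
        for s in range(k):
            partial[node, s] = 1.0
        for ci in range(child_off[node], child_off[node + 1]):
            c = child_flat[ci]
            for s in range(k):
                msg = 0.0
                for t in range(k):
                    msg += P[c, s, t] * partial[c, t]
                partial[node, s] *= msg
        m = partial[node, 0]
        for s in range(1, k):
            if partial[node, s] > m:
                m = partial[node, s]
        if m <= 0.0:
            return -np.inf
        for s in range(k):
            partial[node, s] /= m
        logsc += np.log(m)
    root = order[order.shape[0] - 1]
    lik = 0.0
    for s in range(k):
        lik += root_dist[s] * partial[root, s]
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + logsc


@dataclass
class _PruneCache:
    order: np.ndarray            # postorder node ids
    child_flat: np.ndarray
    child_off: np.ndarray
    edge_nodes: np.ndarray
    levels: list                 # list of (parent_ids, [child_arrays per slot])

    @classmethod
    def build(cls, tree: PhyloTree) -> "_PruneCache":
        ch = tree.children()
        order = tree.postorder()
        child_off = np.zeros(tree.n_nodes + 1, dtype=np.int64)
        for n in range(tree.n_nodes):
            child_off[n + 1] = child_off[n] + len(ch[n])
        child_flat = np.array([c for n in range(tree.n_nodes) for c in ch[n]],
                              dtype=np.int64) if child_off[-1] else \
            np.zeros(0, dtype=np.int64)
        level = np.zeros(tree.n_nodes, dtype=np.int64)
        for node in order:
            if ch[node]:
                level[node] = 1 + max(level[c] for c in ch[node])
        levels = []
        for lv in range(1, level.max() + 1):
            parents = np.flatnonzero(level == lv)
            parents = parents[[len(ch[p]) > 0 for p in parents]]
            max_slots = max(len(ch[p]) for p in parents)
            slots = []
            for s in range(max_slots):
                slots.append(np.array([ch[p][s] if s < len(ch[p]) else -1
                                       for p in parents]))
            levels.append((parents, slots))
        edge_nodes = np.array([n for n in range(tree.n_nodes)
                               if tree.parent[n] >= 0])
        return cls(order, child_flat, child_off, edge_nodes, levels)


_cache_store: dict[int, tuple[PhyloTree, _PruneCache]] = {}


def _get_cache(tree: PhyloTree) -> _PruneCache:
    key = id(tree)
    hit = _cache_store.get(key)
    if hit is not None and hit[0] is tree:
        return hit[1]
    cache = _PruneCache.build(tree)
    if len(_cache_store) > 64:
        _cache_store.clear()
    _cache_store[key] = (tree, cache)
    return cache


def pruning_loglik(tree: PhyloTree, trait, model: RateModel | np.ndarray,
                   root_dist: np.ndarray | None = None) -> float:
    """Felsenstein pruning log-likelihood of a discrete trait on a tree.

    ``trait`` is either a mapping/Series of tip states (ints, ambiguity sets,
    or partial vectors) or a precomputed (n_tips, k) partials array.
    """
    if isinstance(model, RateModel):
        Q = model.q_matrix()
        if root_dist is None:
            root_dist = model.root_distribution()
    else:
        Q = np.asarray(model, dtype=float)
        if root_dist is None:
            root_dist = np.full(Q.shape[0], 1.0 / Q.shape[0])
    k = Q.shape[0]
    if isinstance(trait, np.ndarray) and trait.ndim == 2:
        partials_tips = trait
    else:
        partials_tips = tip_partials(tree, trait, k)

    cache = _get_cache(tree)
    P_all = np.empty((tree.n_nodes, k, k))
    en = cache.edge_nodes
    P_all[en] = transition_matrices(Q, tree.blen[en])
    partial = np.empty((tree.n_nodes, k))
    partial[: tree.n_tips] = partials_tips
    root_dist = np.asarray(root_dist, dtype=float)

    if _HAVE_NUMBA:
        return float(_prune_kernel(cache.order, cache.child_flat,
                                   cache.child_off, tree.n_tips, P_all,
                                   partial, root_dist))

    logsc = np.zeros(tree.n_nodes)
    for parents, slots in cache.levels:
        acc = np.ones((parents.size, k))
        sc = np.zeros(parents.size)
        for kids in slots:
            valid = kids >= 0
            kv = kids[valid]
            msg = np.einsum("eij,ej->ei", P_all[kv], partial[kv])
            acc[valid] *= msg
            sc[valid] += logsc[kv]
        m = acc.max(axis=1)
        if (m <= 0).any():
            return -np.inf
        acc /= m[:, None]
        partial[parents] = acc
        logsc[parents] = sc + np.log(m)
    root = tree.root
    lik = float(root_dist @ partial[root])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logsc[root])


# ---- maximum likelihood --------------------------------------------------


def fit_ml_discrete(tree: PhyloTree, trait, kind: str = "ER",
                    states=None, n_restarts: int = 10, seed: int = 0,
                    root_rule="uniform") -> FitResult:
    """Maximize the pruning likelihood over non-negative rates.

    Optimization is on the log-rate scale from seeded random restarts;
    standard errors come from the numerical Hessian at the optimum (delta
    method back to the rate scale).
    """
    import pandas as pd

    if states is None:
        vals = set()
        items = trait.items() if not isinstance(trait, pd.Series) else trait.items()
        for _, v in items:
            if np.isscalar(v) and not isinstance(v, (set, frozenset)):
                vals.add(int(v))
            else:
                vals.update(int(s) for s in v)
        states = tuple(range(max(vals) + 1))
    k = len(states)
    template = build_rate_matrix(kind, states, np.ones(k * (k - 1) if kind == "ARD"
                                                       else (4 if kind == "IC" else 1)),
                                 root_rule=root_rule)
    part = tip_partials(tree, trait, k)
    observed_states = np.unique(np.argmax(part, axis=1)[part.sum(axis=1) == 1])
    n_free = template.n_free

    def nll(logr):
        m = template.with_rates(np.exp(logr))
        return -pruning_loglik(tree, part, m)

    rng = np.random.default_rng(seed)
    total_len = tree.blen.sum()
    base = np.log(max(len(observed_states), 1) / max(total_len, 1e-9))
    best = None
    for r in range(n_restarts):
        x0 = base + (rng.normal(scale=1.5, size=n_free) if r else np.zeros(n_free))
        res = scipy.optimize.minimize(nll, x0, method="L-BFGS-B",
                                      options={"maxiter": 500})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    rates = np.exp(best.x)
    # curvature-based SEs on rate scale via numerical Hessian of nll in rates
    se = np.full(n_free, np.nan)
    try:
        h = np.maximum(1e-5, 1e-4 * rates)

        def nll_r(rv):
            return -pruning_loglik(tree, part, template.with_rates(np.maximum(rv, 1e-300)))

        H = np.zeros((n_free, n_free))
        f0 = nll_r(rates)
        for i in range(n_free):
            for j in range(i, n_free):
                ei = np.zeros(n_free); ei[i] = h[i]
                ej = np.zeros(n_free); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    nll_r(rates + ei + ej) - nll_r(rates + ei) - nll_r(rates + ej) + f0
                ) / (h[i] * h[j])
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        pass
    boundary = bool((rates < 1e-8).any()) or len(observed_states) < 2
    model = template.with_rates(rates)
    return FitResult(model=model, rates=rates, se=se, loglik=-best.fun,
                     converged=bool(best.success), boundary=boundary,
                     n_free=n_free, message=str(best.message))
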