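"""Pagel's Discrete test of correlated evolution for two binary traits,
and the taxonomic-subsampling robustness protocol.

Two binary traits are modeled jointly as a 4-state CTMC over
((0,0),(0,1),(1,0),(1,1)).  Dual transitions (both traits changing at once)
are forbidden.  The independent model constrains each trait's transition
rates to ignore the other trait's state (4 free rates); the dependent model
leaves all 8 single-step rates free.  Evidence for correlated evolution is
Log BF = 2 x (logML dependent - logML independent) > 2, with marginal
likelihoods from stepping-stone sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes_engine import EngineConfig, ModelComparison, log_bayes_factor, \
    stepping_stone_logml
from .ctmc import ZERO, RateModel
from .treeio import PhyloTree, prune_to

__all__ = [
    "build_pair_model",
    "joint_partials",
    "discrete_correlation_test",
    "subsample_robustness",
    "RobustnessReport",
]

# joint state order: index = 2*x + y
_PAIRS = [(0, 0), (0, 1), (1, 0), (1, 1)]
_DUAL = {(0, 3), (3, 0), (1, 2), (2, 1)}

# single-step positions (from, to) and the trait/direction they move
_DEP_POSITIONS = [
    (0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 1), (3, 2),
]
# independent model: 4 marginal rates (x01, x10, y01, y10) tied across the
# other trait's state
_INDEP_TIES = {
    "x01": [(0, 2), (1, 3)],
    "x10": [(2, 0), (3, 1)],
    "y01": [(0, 1), (2, 3)],
    "y10": [(1, 0), (3, 2)],
}


def build_pair_model(kind: str, rates) -> RateModel:
    """Joint 4-state model for a binary trait pair.

    kind="independent": rates = (qx01, qx10, qy01, qy10).
    kind="dependent": 8 rates in the order
    (q01, q02, q10, q13, q20, q23, q31, q32) of joint-state moves, i.e. the
    classic (q12, q13, q21, q24, q31, q34, q42, q43) in 1-based labels.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    partition: dict = {}
    for i in range(4):
        for j in range(4):
            if i != j:
                partition[(i, j)] = ZERO
    if kind == "independent":
        if rates.size != 4:
            raise ValueError("independent model takes 4 rates")
        ratemap = {}
        for name, positions in _INDEP_TIES.items():
            for p in positions:
                partition[p] = name
        ratemap = dict(zip(_INDEP_TIES, rates))
    elif kind == "dependent":
        if rates.size != 8:
            raise ValueError("dependent model takes 8 rates")
        ratemap = {}
        for idx, p in enumerate(_DEP_POSITIONS):
            cls = f"q{p[0]}{p[1]}"
            partition[p] = cls
            ratemap[cls] = float(rates[idx])
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return RateModel(tuple(_PAIRS), partition, ratemap)


def joint_partials(tree: PhyloTree, x, y) -> np.ndarray:
    """(n_tips, 4) joint partial vectors from two binary trait columns.

    Each trait value may be 0/1 or an ambiguity set; the joint partial is
    the outer product of the two marginal indicator vectors.
    """
    def vec(v):
        out = np.zeros(2)
        if np.isscalar(v) and not isinstance(v, (set, frozenset)):
            out[int(v)] = 1.0
        else:
            for s in v:
                out[int(s)] = 1.0
        return out

    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(y, pd.Series):
        y = y.to_dict()
    part = np.zeros((tree.n_tips, 4))
    for i, name in enumerate(tree.tip_labels):
        if name not in x or name not in y:
            raise KeyError(f"tip {name!r} missing from trait data")
        vx, vy = vec(x[name]), vec(y[name])
        part[i] = np.outer(vx, vy).ravel()
        if part[i].sum() == 0:
            raise ValueError(f"tip {name!r} has empty joint state set")
    return part


def _is_constant(col) -> bool:
    vals = set()
    it = col.items() if isinstance(col, pd.Series) else col.items()
    for _, v in it:
        if np.isscalar(v) and not isinstance(v, (set, frozenset)):
            vals.add(int(v))
        else:
            vals.update(int(s) for s in v)
    return len(vals) < 2


def discrete_correlation_test(tree: PhyloTree, x, y,
                              config: EngineConfig | None = None,
                              seed: int | None = None) -> ModelComparison:
    """Compare dependent vs independent joint models of two binary traits.

    Returns a ModelComparison whose log_bf > 2 is read as evidence for
    correlated evolution.  Constant traits make the test undefined.
    """
    if _is_constant(x) or _is_constant(y):
        raise ValueError("correlation test undefined for a constant trait")
    config = config or EngineConfig.desk()
    seed = config.seed if seed is None else seed
    part = joint_partials(tree, x, y)
    dep = build_pair_model("dependent", np.full(8, 1.0))
    indep = build_pair_model("independent", np.full(4, 1.0))
    logml_dep = stepping_stone_logml(tree, part, dep, config, seed=seed)
    logml_ind = stepping_stone_logml(tree, part, indep, config, seed=seed + 1)
    return log_bayes_factor(logml_dep, logml_ind)


@dataclass
class RobustnessReport:
    """Per-subset correlated-evolution calls from taxonomic subsampling."""

    rows: pd.DataFrame      # fraction, replicate, seed, logml_dep, logml_indep, log_bf, call
    percent_dependent: float
    n_attempted: int
    n_skipped: int
    engine_profile: str = "quick"


def subsample_robustness(tree: PhyloTree, x, y,
                         fractions=(0.5, 0.55, 0.6, 0.65, 0.7, 0.75,
                                    0.8, 0.85, 0.9, 0.95),
                         replicates: int = 10,
                         config: EngineConfig | None = None,
                         seed: int = 0) -> RobustnessReport:
    """Repeat the correlation test on random species subsets.

    For each (fraction, replicate) species are sampled without replacement,
    the tree is pruned, and the dependent/independent comparison re-run.
    Subsets leaving either trait constant are skipped and logged.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or EngineConfig.quick()
    rng = np.random.default_rng(seed)
    if isinstance(x, dict):
        x = pd.Series(x)
    if isinstance(y, dict):
        y = pd.Series(y)
    species = list(tree.tip_labels)
    rows = []
    n_skip = 0
    for frac in fractions:
        for rep in range(replicates):
            sub_seed = int(rng.integers(2**31 - 1))
            n_keep = max(3, int(round(frac * len(species))))
            if n_keep >= len(species):
                sub = species
                subtree = tree
            else:
                sub = list(rng.choice(species, size=n_keep, replace=False))
                subtree = prune_to(tree, sub)
            xs, ys = x.loc[sub], y.loc[sub]
            try:
                comp = discrete_correlation_test(subtree, xs, ys, config,
                                                 seed=sub_seed)
            except ValueError:
                n_skip += 1
                continue
            rows.append(dict(fraction=frac, replicate=rep, seed=sub_seed,
                             logml_dep=comp.logml_complex,
                             logml_indep=comp.logml_simple,
                             log_bf=comp.log_bf,
                             call=comp.log_bf > 2))
    df = pd.DataFrame(rows)
    pct = float(100.0 * df["call"].mean()) if len(df) else float("nan")
    return RobustnessReport(df, pct, len(rows) + n_skip, n_skip)
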