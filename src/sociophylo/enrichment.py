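"""SUMSTAT gene-set enrichment over per-gene scores with empirical nulls,
confounder rescaling, and overlap pruning.

A gene set's SUMSTAT score is the sum of its member gene scores (posterior
means from the expression models, or selection-intensity K values supplied
externally).  Significance is empirical: the observed sum is compared with
sums of random same-size gene sets drawn from the background, with the +1
tail correction so p is never 0.  When scores correlate with a confounder
(gene length or species count), scores are re-centered and re-scaled within
equal-occupancy confounder bins before testing (RescaleBins).  Overlapping
sets are disambiguated by iterative pruning: the most significant set is
frozen and its genes removed from all remaining sets before re-testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "EnrichmentResult",
    "prepare_scores",
    "rescale_bins",
    "sumstat",
    "empirical_null_p",
    "prune_and_test",
]


@dataclass
class EnrichmentResult:
    set_id: str
    score: float
    p_value: float
    direction: str
    n_draws: int
    pruning_round: int
    set_size: int
    coverage: int              # members present in the score table


def prepare_scores(scores: pd.Series, direction: str = "two-sided") -> pd.Series:
    """Direction-specific score preparation.

    positive: negative scores set to 0; negative: positive scores set to 0
    and the rest negated (so larger means more extreme); two-sided: identity.
    """
    if direction == "two-sided":
        return scores.copy()
    out = scores.copy()
    if direction == "positive":
        out[out < 0] = 0.0
    elif direction == "negative":
        out[out > 0] = 0.0
        out = -out
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out


def rescale_bins(scores: pd.Series, confounder: pd.Series, n_bins: int = 20,
                 alpha: float = 0.05, min_bin: int = 5
                 ) -> tuple[pd.Series, dict]:
    """Remove a score-confounder trend by within-bin standardization.

    Tests the Pearson correlation between score and confounder; if
    p < alpha, genes are ordered by the confounder, split into ``n_bins``
    equal-occupancy bins (bins under ``min_bin`` genes merged with a
    neighbor), and scores are re-centered/re-scaled within bin to the global
    mean and SD.  Otherwise the scores pass through unchanged.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    confounder = confounder.loc[scores.index]
    if confounder.isna().any():
        raise ValueError("confounder must be complete")
    r, p = scipy.stats.pearsonr(scores, confounder)
    report = {"correlation": float(r), "p_value": float(p),
              "rescaled": bool(p < alpha), "n_bins_used": 0, "merged": 0}
    if p >= alpha:
        return scores.copy(), report
    order = confounder.rank(method="first").astype(int) - 1
    edges = np.linspace(0, len(scores), n_bins + 1).astype(int)
    bin_of = np.searchsorted(edges[1:-1], order.to_numpy(), side="right")
    # merge undersized bins with their left neighbor
    merged = 0
    sizes = np.bincount(bin_of, minlength=n_bins)
    for b in range(n_bins):
        if 0 < sizes[b] < min_bin:
            tgt = b - 1 if b > 0 else b + 1
            bin_of[bin_of == b] = tgt
            sizes = np.bincount(bin_of, minlength=n_bins)
            merged += 1
    gmean, gsd = scores.mean(), scores.std(ddof=0)
    out = scores.copy().astype(float)
    used = 0
    for b in np.unique(bin_of):
        m = bin_of == b
        vals = scores.to_numpy()[m]
        sd = vals.std()
        if sd == 0:
            continue    # degenerate bin left unchanged
        out.iloc[np.flatnonzero(m)] = (vals - vals.mean()) / sd * gsd + gmean
        used += 1
    report["n_bins_used"] = used
    report["merged"] = merged
    return out, report


def sumstat(scores: pd.Series, members) -> tuple[float, int]:
    """Sum of member scores; absent genes contribute 0.

    Returns (score, coverage), coverage = number of members found in the
    score table.
    """
    members = list(members)
    if not members:
        raise ValueError("empty gene set")
    present = scores.index.intersection(members)
    return float(scores.loc[present].sum()), int(len(present))


def empirical_null_p(scores: pd.Series, set_size: int, observed: float,
                     draws: int = 2000, side: str = "upper",
                     seed: int = 0) -> tuple[float, dict]:
    """Empirical p against random same-size gene sets.

    p = (1 + #{null as or more extreme}) / (draws + 1).
    """
    if draws < 100:
        raise ValueError("need at least 100 null draws")
    n = len(scores)
    if set_size > n:
        raise ValueError("set size exceeds background")
    rng = np.random.default_rng(seed)
    vals = scores.to_numpy(dtype=float)
    nulls = np.empty(draws)
    if set_size * draws <= 4_000_000:
        keys = rng.random((draws, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        nulls = vals[idx].sum(axis=1)
    else:
        for i in range(draws):
            nulls[i] = vals[rng.choice(n, size=set_size, replace=False)].sum()
    tol = 1e-9 * max(1.0, abs(observed))   # ties robust to summation order
    if side == "upper":
        hits = int((nulls >= observed - tol).sum())
    elif side == "lower":
        hits = int((nulls <= observed + tol).sum())
    else:
        raise ValueError(f"unknown side {side!r}")
    p = (1.0 + hits) / (draws + 1.0)
    summary = {"null_mean": float(nulls.mean()), "null_sd": float(nulls.std()),
               "draws": draws}
    return p, summary


def prune_and_test(collection: dict, scores: pd.Series, draws: int = 2000,
                   alpha: float = 0.05, side: str = "upper",
                   seed: int = 0) -> pd.DataFrame:
    """Iterative test-freeze-prune enrichment over a gene-set collection.

    Round r: every remaining set is tested at its current (possibly reduced)
    size; the most significant set with p < alpha is frozen and its genes
    removed from all remaining sets; repeat until nothing reaches alpha.
    The returned table carries one row per set with its final statistics,
    frozen sets marked ``significant`` with their pruning round.
    """
    rng = np.random.default_rng(seed)
    remaining = {k: list(v) for k, v in collection.items() if len(v) > 0}
    results: dict[str, EnrichmentResult] = {}
    round_no = 0
    while remaining:
        round_no += 1
        stats = {}
        for sid, members in remaining.items():
            if not members:
                continue
            obs, cov = sumstat(scores, members)
            p, _ = empirical_null_p(scores, max(cov, 1), obs, draws, side,
                                    seed=int(rng.integers(2**31 - 1)))
            stats[sid] = (p, obs, cov, len(members))
        if not stats:
            break
        best = min(stats, key=lambda s: (stats[s][0], -abs(stats[s][1])))
        p_best, obs_best, cov_best, size_best = stats[best]
        if p_best >= alpha:
            for sid, (p, obs, cov, size) in stats.items():
                results[sid] = EnrichmentResult(
                    sid, obs, p, side, draws, 0, size, cov)
            break
        results[best] = EnrichmentResult(best, obs_best, p_best, side, draws,
                                         round_no, size_best, cov_best)
        pruned_genes = set(remaining.pop(best))
        for sid in list(remaining):
            remaining[sid] = [g for g in remaining[sid] if g not in pruned_genes]
            if not remaining[sid]:
                results[sid] = EnrichmentResult(sid, 0.0, 1.0, side, draws,
                                                0, 0, 0)
                del remaining[sid]
    rows = [vars(r) for r in results.values()]
    df = pd.DataFrame(rows).sort_values("p_value").reset_index(drop=True)
    df["significant"] = df["pruning_round"] > 0
    return df
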