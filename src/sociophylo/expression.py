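"""Count filtering and TMM-RPKM-log2 normalization of RNA-seq count
matrices, producing the per-species expression panel consumed by the
phylogenetic mixed models.

Filters, in order: low-count genes (counts < 10 in more than 3 samples),
single-gene library hogs (a gene exceeding 5% of any sample's total), and
species coverage (orthologs detected in at least 70% of species).
Library sizes are scaled by the trimmed mean of M-values (TMM: 30% trim on
log-ratios, 5% on abundance, precision weights, factors normalized to
geometric mean 1); expression is then reads per kilobase per million mapped
reads on the TMM-effective library size, log2(RPKM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "FilterReport",
    "filter_counts",
    "filter_species_coverage",
    "tmm_factors",
    "normalize_rpkm_log",
    "collapse_to_species",
]


@dataclass
class FilterReport:
    removed: pd.DataFrame        # gene, reason
    n_input: int
    n_kept: int
    flagged_empty: bool = False


def filter_counts(counts: pd.DataFrame, low_count: int = 10,
                  low_samples: int = 3, high_fraction: float = 0.05
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove low-count and library-dominating genes.

    A gene is low if its count is below ``low_count`` in strictly more than
    ``low_samples`` samples; high if its count exceeds ``high_fraction`` of
    any sample's total.  Low is applied first, then high, matching the
    reported removal bookkeeping.
    """
    if low_count <= 0 or low_samples < 0 or not 0 < high_fraction < 1:
        raise ValueError("invalid filter thresholds")
    removed = []
    low_mask = (counts < low_count).sum(axis=1) > low_samples
    for g in counts.index[low_mask]:
        removed.append((g, "low_count"))
    kept = counts.loc[~low_mask]
    totals = kept.sum(axis=0)
    high_mask = (kept.div(totals, axis=1) > high_fraction).any(axis=1)
    for g in kept.index[high_mask]:
        removed.append((g, "high_fraction"))
    kept = kept.loc[~high_mask]
    report = FilterReport(
        removed=pd.DataFrame(removed, columns=["gene", "reason"]),
        n_input=len(counts), n_kept=len(kept),
        flagged_empty=len(kept) == 0,
    )
    return kept, report


def filter_species_coverage(presence: pd.DataFrame,
                            min_fraction: float = 0.70) -> pd.Index:
    """Genes detected in at least ceil(min_fraction * n_species) species.

    ``presence`` is a boolean genes x species table (True = detected).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_species = presence.shape[1]
    need = int(np.ceil(min_fraction * n_species))
    keep = presence.sum(axis=1) >= need
    return presence.index[keep]


def _upper_quartile_reference(counts: np.ndarray) -> int:
    """edgeR's reference pick: sample whose 75th percentile of scaled counts
    is closest to the mean across samples."""
    totals = counts.sum(axis=0)
    uq = np.array([np.quantile(counts[:, j] / totals[j], 0.75)
                   for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(counts: pd.DataFrame, trim_logfc: float = 0.30,
                trim_abs: float = 0.05,
                reference: int | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample vs the reference: genes with positive counts in both
    enter with M (log2 ratio of relative abundance), A (mean log2 relative
    abundance) and delta-method precision weights; the top/bottom 30% by M
    and 5% by A are discarded and the factor is 2**(weighted mean of the
    surviving M values).
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = X.sum(axis=0)
    active = totals > 0
    if not active.all():
        import warnings

        warnings.warn("samples with all-zero counts excluded from TMM",
                      stacklevel=2)
    ref = _upper_quartile_reference(X[:, active]) if reference is None \
        else reference
    ref_idx = np.flatnonzero(active)[ref] if reference is None else reference
    xr = X[:, ref_idx]
    Nr = totals[ref_idx]
    log_factors = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if not active[j]:
            continue
        if j == ref_idx:
            continue
        x = X[:, j]
        N = totals[j]
        ok = (x > 0) & (xr > 0)
        if ok.sum() < 10:
            continue
        p, pr = x[ok] / N, xr[ok] / Nr
        M = np.log2(p / pr)
        A = 0.5 * np.log2(p * pr)
        w = (N - x[ok]) / (N * x[ok]) + (Nr - xr[ok]) / (Nr * xr[ok])
        # double trim: drop extreme M (30% total) and extreme A (5% total)
        n = M.size
        lo_m, hi_m = np.floor(n * trim_logfc / 2), np.ceil(n * (1 - trim_logfc / 2))
        lo_a, hi_a = np.floor(n * trim_abs / 2), np.ceil(n * (1 - trim_abs / 2))
        rank_m = rankdata(M)
        rank_a = rankdata(A)
        keep = (rank_m > lo_m) & (rank_m <= hi_m) & \
               (rank_a > lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            continue
        log_factors[j] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** log_factors
    # normalize to geometric mean 1 over active samples
    gm = np.exp(np.log(factors[active]).mean())
    factors = factors / gm
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_rpkm_log(counts: pd.DataFrame, gene_lengths: pd.Series,
                       factors: pd.Series | None = None) -> pd.DataFrame:
    """log2(RPKM + 1) on TMM-effective library sizes.

    RPKM_gs = count_gs / (effective_size_s / 1e6) / (length_g / 1e3), with
    effective size = library size x TMM factor.
    """
    lengths = gene_lengths.loc[counts.index].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0).to_numpy(dtype=float)
    f = factors.loc[counts.columns].to_numpy(dtype=float) if factors is not None \
        else np.ones(counts.shape[1])
    eff = totals * f
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    rpkm = counts.to_numpy(dtype=float) / (eff / 1e6)[None, :] / \
        (lengths / 1e3)[:, None]
    out = pd.DataFrame(np.log2(rpkm + 1.0), index=counts.index,
                       columns=counts.columns)
    out.attrs["tmm_factors"] = f.tolist()
    out.attrs["effective_sizes"] = eff.tolist()
    return out


def collapse_to_species(norm: pd.DataFrame, sample_species: pd.Series,
                        how: str = "mean") -> pd.DataFrame:
    """Collapse multiple samples per species to one expression value
    (mean or median of log2 values after normalization)."""
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    groups = norm.T.groupby(sample_species.loc[norm.columns])
    return (groups.mean() if how == "mean" else groups.median()).T
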