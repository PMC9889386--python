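"""Species-trait table handling: loading, state coding, derived longevity
measures, cutoffs, and descriptive summaries.

A trait table is a pandas DataFrame keyed by a ``species`` column with, where
present: ``social_states`` (a non-empty subset of {solitary, pair-living,
group-living}, stored as semicolon-separated tokens on disk and as frozensets
in memory), ``lifespan`` (maximum recorded lifespan, years), ``body_mass``
(adult body mass, grams), and categorical covariates (activity, diet,
lifestyle, fossoriality).

Relative longevity is the body-mass-adjusted residual
lifespan / (4.88 * body_mass^0.153), the allometric baseline used by the
AnAge database.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "SOCIAL_STATES",
    "load_trait_table",
    "relative_longevity",
    "binarize_longevity",
    "encode_social",
    "quantile_cutoffs",
    "dataset_summary",
    "DatasetSummary",
]

SOCIAL_STATES = ("solitary", "pair-living", "group-living")
_STATE_INDEX = {s: i for i, s in enumerate(SOCIAL_STATES)}


def load_trait_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a trait table (TSV/CSV with header) and parse social states.

    Species names are normalized with underscores for spaces; the
    ``social_states`` column becomes frozensets of canonical state names.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "species" not in df.columns:
        raise ValueError("trait table needs a 'species' column")
    df["species"] = df["species"].str.replace(" ", "_")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species: {dups[:5]}")
    if "social_states" in df.columns:
        df["social_states"] = df["social_states"].map(parse_social)
    return df


def parse_social(value) -> frozenset:
    if isinstance(value, (set, frozenset)):
        states = frozenset(value)
    else:
        states = frozenset(tok.strip() for tok in str(value).split(";")
                           if tok.strip())
    unknown = states - set(SOCIAL_STATES)
    if unknown:
        raise ValueError(f"unknown social states {sorted(unknown)}")
    if not states:
        raise ValueError("empty social state set")
    return states


def relative_longevity(lifespan, body_mass):
    """Body-mass-adjusted residual longevity:
    lifespan / (4.88 * body_mass**0.153), mass in grams, lifespan in years."""
    lifespan = np.asarray(lifespan, dtype=float)
    body_mass = np.asarray(body_mass, dtype=float)
    if (lifespan <= 0).any() or (body_mass <= 0).any():
        raise ValueError("lifespan and body mass must be positive")
    out = lifespan / (4.88 * body_mass ** 0.153)
    return float(out) if out.ndim == 0 else out


def quantile_cutoffs(values) -> tuple[float, float]:
    """(median, third quartile) by linear interpolation between order
    statistics (the default quantile convention of mainstream statistics
    environments); recorded so binarization cutoffs are reproducible."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 4:
        raise ValueError("need at least 4 values")
    return float(np.quantile(values, 0.5)), float(np.quantile(values, 0.75))


def binarize_longevity(table: pd.DataFrame, cutoff: float,
                       mode: str = "absolute"
                       ) -> tuple[pd.Series, dict]:
    """Binary long-lived (1) / short-lived (0) coding at a cutoff.

    mode="absolute" thresholds lifespan in years; mode="relative" thresholds
    the body-mass residual.  Long-lived means strictly greater than the
    cutoff.  Rows with missing inputs are excluded and reported.
    """
    if mode == "absolute":
        vals = table["lifespan"]
    elif mode == "relative":
        vals = pd.Series(
            relative_longevity(table["lifespan"].fillna(1.0),
                               table["body_mass"].fillna(1.0)),
            index=table.index)
        vals[table["lifespan"].isna() | table["body_mass"].isna()] = np.nan
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ok = vals.notna()
    coded = (vals[ok] > cutoff).astype(int)
    if "species" in table.columns:
        coded.index = table.loc[ok, "species"]
    counts = {
        "long": int(coded.sum()),
        "short": int((coded == 0).sum()),
        "excluded": int((~ok).sum()),
        "cutoff": cutoff,
        "mode": mode,
    }
    return coded.rename("long_lived"), counts


def encode_social(table: pd.DataFrame, scheme: str,
                  polymorphic: str = "ambiguous") -> pd.Series:
    """Code social organization for the likelihood machinery.

    scheme "three-state" keeps the full state set (multi-state species
    become ambiguity sets over state indices 0=solitary, 1=pair-living,
    2=group-living).  Binary schemes ("solitary-vs-rest", "pair-vs-rest",
    "group-vs-rest") code membership of the focal state; multi-state species
    containing the focal state are coded as the ambiguity set {0, 1} under
    ``polymorphic="ambiguous"`` or removed under ``"drop"`` (the uni-state
    species subset).
    """
    if polymorphic not in ("ambiguous", "drop"):
        raise ValueError("polymorphic must be 'ambiguous' or 'drop'")
    focal = {"solitary-vs-rest": "solitary", "pair-vs-rest": "pair-living",
             "group-vs-rest": "group-living"}
    idx = table["species"] if "species" in table.columns else table.index
    states = table["social_states"].map(parse_social)
    if scheme == "three-state":
        coded = states.map(lambda s: frozenset(_STATE_INDEX[x] for x in s))
        coded.index = idx
        return coded.rename("social")
    if scheme not in focal:
        raise ValueError(f"unknown scheme {scheme!r}")
    f = focal[scheme]
    out = {}
    for sp, s in zip(idx, states):
        if len(s) == 1:
            out[sp] = 1 if f in s else 0
        elif f in s:
            if polymorphic == "drop":
                continue
            out[sp] = frozenset({0, 1})
        else:
            out[sp] = 0
    return pd.Series(out, name=scheme)


@dataclass
class DatasetSummary:
    n_species: int
    per_state_counts: dict
    n_multi_state: int
    lifespan_mean: float
    lifespan_sd: float
    lifespan_median: float
    lifespan_iqr: tuple[float, float]
    spearman_lifespan_mass: float
    spearman_p: float
    order_representation: pd.DataFrame | None = None
    wilcoxon_stat: float = float("nan")
    wilcoxon_p: float = float("nan")
    wilcoxon_note: str = ""


def dataset_summary(table: pd.DataFrame,
                    reference_table: pd.DataFrame | None = None
                    ) -> DatasetSummary:
    """Descriptive summary: per-state counts (multi-state species count in
    every state they occupy), lifespan statistics, the Spearman rank
    correlation of lifespan with body mass, and — given a reference table
    with an ``order`` column — per-order representation ratios compared by
    an exact Wilcoxon signed-rank test for small n."""
    states = table["social_states"].map(parse_social)
    counts = {s: int(states.map(lambda x: s in x).sum()) for s in SOCIAL_STATES}
    n_multi = int(states.map(lambda x: len(x) > 1).sum())
    ls = table["lifespan"].dropna()
    q1, q3 = np.quantile(ls, [0.25, 0.75])
    both = table.dropna(subset=["lifespan", "body_mass"])
    rho, rho_p = scipy.stats.spearmanr(both["lifespan"], both["body_mass"])

    order_rep = None
    wstat = wp = float("nan")
    note = ""
    if reference_table is not None and "order" in table.columns \
            and "order" in reference_table.columns:
        a = table["order"].value_counts(normalize=True)
        b = reference_table["order"].value_counts(normalize=True)
        orders = sorted(set(a.index) | set(b.index))
        order_rep = pd.DataFrame({
            "ratio_sample": [a.get(o, 0.0) for o in orders],
            "ratio_reference": [b.get(o, 0.0) for o in orders],
        }, index=orders)
        diffs = order_rep["ratio_sample"] - order_rep["ratio_reference"]
        nz = diffs[diffs != 0]
        if len(nz) == 0:
            note = "degenerate: all paired differences are zero"
        else:
            mode = "exact" if len(nz) <= 25 else "approx"
            res = scipy.stats.wilcoxon(nz, mode=mode)
            wstat, wp = float(res.statistic), float(res.pvalue)
    return DatasetSummary(
        n_species=len(table),
        per_state_counts=counts,
        n_multi_state=n_multi,
        lifespan_mean=float(ls.mean()),
        lifespan_sd=float(ls.std()),
        lifespan_median=float(ls.median()),
        lifespan_iqr=(float(q1), float(q3)),
        spearman_lifespan_mass=float(rho),
        spearman_p=float(rho_p),
        order_representation=order_rep,
        wilcoxon_stat=wstat,
        wilcoxon_p=wp,
        wilcoxon_note=note,
    )
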