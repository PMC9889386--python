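"""MCMC samplers over CTMC rate parameters and marginal-likelihood
estimation by stepping-stone sampling.

The samplers follow the hyper-prior scheme used throughout the analysis:
each transition rate has an Exponential(m) prior whose mean m is itself
given a uniform hyperprior (default U(0, 2)).  Metropolis-Hastings proposals
act on log-rates with scales auto-tuned during burn-in only.  The
reversible-jump sampler explores partitions of the off-diagonal rate
positions into shared rate classes plus a "zero" class, reporting posterior
model frequencies.

Marginal likelihoods come from the stepping-stone path of power posteriors
between prior (beta = 0) and posterior (beta = 1), with stone temperatures
beta_k = (k/K)^(1/0.3) concentrating stones near the prior.  Two engine
profiles are provided: "desk" (50 stones x 1,000 iterations; chains of
200k/50k burn-in/thin 100) for routine work, and "paper" (1000 x 10,000;
100M/50M/100) matching the full-scale study protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ctmc import ZERO, RateModel, pruning_loglik, tip_partials
from .treeio import PhyloTree

__all__ = [
    "EngineConfig",
    "Chain",
    "ChainDiagnostics",
    "ModelComparison",
    "run_mcmc",
    "run_rjmcmc",
    "stepping_stone_logml",
    "stepping_stone_generic",
    "log_bayes_factor",
    "chain_diagnostics",
    "evidence_category",
]


@dataclass
class EngineConfig:
    iterations: int = 200_000
    burn_in: int = 50_000
    thinning: int = 100
    stones: int = 50
    iterations_per_stone: int = 1_000
    seed: int = 0
    hyperprior: tuple[float, float] = (0.0, 2.0)

    @classmethod
    def desk(cls, seed: int = 0) -> "EngineConfig":
        return cls(seed=seed)

    @classmethod
    def paper(cls, seed: int = 0) -> "EngineConfig":
        return cls(iterations=100_000_000, burn_in=50_000_000, thinning=100,
                   stones=1000, iterations_per_stone=10_000, seed=seed)

    @classmethod
    def quick(cls, seed: int = 0) -> "EngineConfig":
        """Reduced profile for batch experiments (subsampling robustness,
        simulation studies): 12 stones x 200 iterations."""
        return cls(iterations=4_000, burn_in=1_000, thinning=2,
                   stones=12, iterations_per_stone=200, seed=seed)


@dataclass
class Chain:
    draws: np.ndarray                 # (n_draws, n_params)
    param_names: list[str]
    loglik: np.ndarray
    settings: EngineConfig
    model_ids: list[str] | None = None
    hyper_mean: np.ndarray | None = None
    acceptance: float = float("nan")
    flagged: bool = False

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def posterior_mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)


@dataclass
class ChainDiagnostics:
    ess: np.ndarray
    rhat: np.ndarray | None
    harmonic_mean_stable: bool
    param_names: list[str] = field(default_factory=list)


@dataclass
class ModelComparison:
    logml_complex: float
    logml_simple: float
    log_bf: float
    favored: str
    category: str
    logml_sd: tuple[float, float] | None = None


def evidence_category(log_bf: float) -> str:
    if log_bf < 2:
        return "simple"
    if log_bf < 5:
        return "positive"
    if log_bf <= 10:
        return "strong"
    return "very strong"


def log_bayes_factor(logml_complex: float, logml_simple: float) -> ModelComparison:
    """Log BF = 2 x (log marginal likelihood complex - simple), with the
    standard evidence categories (2 / 5-10 / >10)."""
    if not (math.isfinite(logml_complex) and math.isfinite(logml_simple)):
        raise ValueError("log marginal likelihoods must be finite")
    bf = 2.0 * (logml_complex - logml_simple)
    favored = "complex" if bf > 2 else "simple"
    return ModelComparison(logml_complex, logml_simple, bf, favored,
                           evidence_category(bf))


# ---- fixed-dimension MH over rates ---------------------------------------


class _RateTarget:
    """Posterior over log-rates of a fixed RateModel partition, with the
    exponential prior and uniform hyperprior on its mean."""

    def __init__(self, tree: PhyloTree, trait, model: RateModel,
                 hyperprior=(0.0, 2.0)):
        self.tree = tree
        self.model = model
        self.k = model.k
        self.partials = (trait if isinstance(trait, np.ndarray) and trait.ndim == 2
                         else tip_partials(tree, trait, self.k))
        self.names = model.class_ids()
        self.n = len(self.names)
        self.a, self.b = hyperprior

    def loglik(self, rates: np.ndarray) -> float:
        return pruning_loglik(self.tree, self.partials,
                              self.model.with_rates(rates))

    def logprior(self, rates: np.ndarray, m: float) -> float:
        if not (self.a < m <= self.b) or (rates < 0).any():
            return -np.inf
        return float(-self.n * np.log(m) - rates.sum() / m)

    def sample_prior(self, rng) -> tuple[np.ndarray, float]:
        m = rng.uniform(max(self.a, 1e-6), self.b)
        return rng.exponential(m, size=self.n), m


def _mh_rates(target: _RateTarget, rng, n_iter: int, burn_in: int, thinning: int,
              beta: float = 1.0, init=None, collect: bool = True):
    """Adaptive MH on log-rates; hyperprior mean updated by its own MH step.

    Returns (draws, logliks, hyper, acc_rate, state) where state can warm-
    start the next stone.
    """
    if init is None:
        rates, m = target.sample_prior(rng)
        rates = np.maximum(rates, 1e-6)
    else:
        rates, m = init
        rates = np.asarray(rates, dtype=float).copy()
    ll = target.loglik(rates)
    lp = target.logprior(rates, m)
    step = np.full(target.n, 0.6)
    mstep = 0.4
    acc = np.zeros(target.n)
    tries = np.zeros(target.n)
    draws, lls, hypers = [], [], []
    n_total = burn_in + n_iter
    for it in range(n_total):
        # rate updates, one coordinate at a time (multiplicative proposal)
        for j in range(target.n):
            prop = rates.copy()
            prop[j] = rates[j] * np.exp(step[j] * rng.standard_normal())
            ll_p = target.loglik(prop)
            lp_p = target.logprior(prop, m)
            # log proposal asymmetry for multiplicative move: log(prop/cur)
            log_alpha = (beta * (ll_p - ll) + lp_p - lp
                         + np.log(prop[j] / rates[j]))
            tries[j] += 1
            if np.log(rng.uniform()) < log_alpha:
                rates, ll, lp = prop, ll_p, lp_p
                acc[j] += 1
        # hyperprior mean update (likelihood-free)
        mp = m * np.exp(mstep * rng.standard_normal())
        lp_p = target.logprior(rates, mp)
        if np.log(rng.uniform()) < lp_p - lp + np.log(mp / m):
            m, lp = mp, lp_p
        # adaptation during burn-in only
        if it < burn_in and (it + 1) % 50 == 0:
            rate_acc = acc / np.maximum(tries, 1)
            step *= np.exp(np.clip(rate_acc - 0.3, -0.5, 0.5))
            step = np.clip(step, 0.01, 5.0)
            acc[:] = 0
            tries[:] = 0
        if collect and it >= burn_in and (it - burn_in) % thinning == 0:
            draws.append(rates.copy())
            lls.append(ll)
            hypers.append(m)
    acc_rate = float((acc / np.maximum(tries, 1)).mean()) if tries.sum() else 0.0
    return (np.array(draws), np.array(lls), np.array(hypers), acc_rate,
            (rates, m))


def run_mcmc(tree: PhyloTree, trait, model: RateModel,
             config: EngineConfig | None = None,
             hyperprior: tuple[float, float] | None = None) -> Chain:
    """Metropolis-Hastings over the rates of a fixed model partition.

    Rates carry an Exponential(m) prior with m ~ Uniform(hyperprior);
    proposal scales are tuned during burn-in only.
    """
    config = config or EngineConfig.desk()
    hp = hyperprior or config.hyperprior
    if not (0 <= hp[0] < hp[1]):
        raise ValueError("hyperprior bounds must satisfy 0 <= a < b")
    rng = np.random.default_rng(config.seed)
    target = _RateTarget(tree, trait, model, hp)
    n_keep = (config.iterations - config.burn_in) // config.thinning
    draws, lls, hypers, acc, _ = _mh_rates(
        target, rng, n_iter=config.iterations - config.burn_in,
        burn_in=config.burn_in, thinning=config.thinning)
    flagged = acc == 0.0
    return Chain(draws[:n_keep], target.names, lls[:n_keep], config,
                 hyper_mean=hypers[:n_keep], acceptance=acc, flagged=flagged)


# ---- stepping stone ------------------------------------------------------


def _beta_ladder(stones: int) -> np.ndarray:
    k = np.arange(stones + 1)
    return (k / stones) ** (1.0 / 0.3)


def stepping_stone_generic(loglik_fn, sample_prior, mh_step, stones: int,
                           iterations_per_stone: int, seed: int = 0,
                           burn_frac: float = 0.25) -> float:
    """Stepping-stone log marginal likelihood for an arbitrary target.

    Parameters
    ----------
    loglik_fn : params -> float
    sample_prior : rng -> params
    mh_step : (params, loglik, beta, rng) -> (params, loglik)
        one sweep of a valid MCMC kernel for the power posterior at beta.
    """
    rng = np.random.default_rng(seed)
    betas = _beta_ladder(stones)
    params = sample_prior(rng)
    ll = loglik_fn(params)
    burn = max(1, int(burn_frac * iterations_per_stone))
    logml = 0.0
    for s in range(stones):
        b_lo, b_hi = betas[s], betas[s + 1]
        samples = np.empty(iterations_per_stone)
        for it in range(burn + iterations_per_stone):
            params, ll = mh_step(params, ll, b_lo, rng)
            if it >= burn:
                samples[it - burn] = ll
        d = b_hi - b_lo
        m = samples.max()
        if not np.isfinite(m):
            return float("nan")
        logml += d * m + np.log(np.mean(np.exp(d * (samples - m))))
    return float(logml)


def stepping_stone_logml(tree: PhyloTree, trait, model: RateModel,
                         config: EngineConfig | None = None,
                         stones: int | None = None,
                         iterations_per_stone: int | None = None,
                         seed: int | None = None) -> float:
    """Stepping-stone marginal likelihood of a discrete-trait model.

    Integrates over both the rates and the hyperprior mean along the power
    posterior path from the prior (beta=0) to the posterior (beta=1).
    """
    config = config or EngineConfig.desk()
    stones = stones or config.stones
    ips = iterations_per_stone or config.iterations_per_stone
    seed = config.seed if seed is None else seed
    if stones < 2:
        raise ValueError("need at least 2 stones")
    rng = np.random.default_rng(seed)
    target = _RateTarget(tree, trait, model, config.hyperprior)
    betas = _beta_ladder(stones)
    state = None
    logml = 0.0
    burn = max(10, ips // 4)
    for s in range(stones):
        b_lo, b_hi = betas[s], betas[s + 1]
        draws, lls, _, _, state = _mh_rates(
            target, rng, n_iter=ips, burn_in=burn, thinning=1,
            beta=b_lo, init=state)
        d = b_hi - b_lo
        m = lls.max()
        if not np.isfinite(m):
            return float("nan")
        logml += d * m + np.log(np.mean(np.exp(d * (lls - m))))
    return float(logml)


# ---- reversible jump -----------------------------------------------------


def _canonical_model_id(assign: list) -> str:
    """Canonical string for a partition: classes renamed in order of first
    appearance, zero class kept as 'Z'."""
    mapping: dict = {}
    out = []
    for a in assign:
        if a == ZERO:
            out.append("Z")
        else:
            if a not in mapping:
                mapping[a] = chr(ord("A") + len(mapping))
            out.append(mapping[a])
    return "".join(out)


def run_rjmcmc(tree: PhyloTree, trait, states, config: EngineConfig | None = None,
               allow_zero: bool = True, positions=None) -> Chain:
    """Reversible-jump MCMC over rate-class partitions of the off-diagonal
    positions of Q (optionally restricted to ``positions``).

    Moves: (i) within-model multiplicative rate updates; (ii) reassignment of
    one position to an existing class, a fresh class (rate drawn from the
    exponential prior, which cancels in the acceptance ratio), or the zero
    class.  The model prior is uniform over attainable partitions.
    """
    config = config or EngineConfig.desk()
    rng = np.random.default_rng(config.seed)
    states = tuple(states)
    k = len(states)
    all_pairs = [(i, j) for i in range(k) for j in range(k) if i != j]
    pairs = [tuple(p) for p in positions] if positions is not None else all_pairs
    fixed_zero = [p for p in all_pairs if p not in pairs]
    n_pos = len(pairs)
    hp = config.hyperprior

    def make_model(assign, rates):
        partition = {p: assign[i] for i, p in enumerate(pairs)}
        for p in fixed_zero:
            partition[p] = ZERO
        return RateModel(states, partition, dict(rates))

    partials = tip_partials(tree, trait, k)

    # init: one shared class
    assign = ["c0"] * n_pos
    m = rng.uniform(max(hp[0], 1e-6), hp[1])
    rates = {"c0": rng.exponential(m)}
    next_class = 1

    def loglik(assign, rates):
        return pruning_loglik(tree, partials, make_model(assign, rates))

    def logprior(rates, m):
        if not (hp[0] < m <= hp[1]):
            return -np.inf
        vals = np.array(list(rates.values()))
        if (vals < 0).any():
            return -np.inf
        return float(-len(vals) * np.log(m) - vals.sum() / m)

    ll = loglik(assign, rates)
    lp = logprior(rates, m)
    step = 0.6
    n_keep = (config.iterations - config.burn_in) // config.thinning
    model_ids: list[str] = []
    lls = np.empty(n_keep)
    mean_rate = np.empty(n_keep)
    kept = 0
    acc_n = 0
    tot_n = 0
    for it in range(config.iterations):
        # -- within-model rate updates
        for cls in list(rates):
            prop = dict(rates)
            prop[cls] = rates[cls] * np.exp(step * rng.standard_normal())
            ll_p = loglik(assign, prop)
            lp_p = logprior(prop, m)
            tot_n += 1
            if np.log(rng.uniform()) < ll_p - ll + lp_p - lp + np.log(prop[cls] / rates[cls]):
                rates, ll, lp = prop, ll_p, lp_p
                acc_n += 1
        # -- hyperprior mean
        mp = m * np.exp(0.4 * rng.standard_normal())
        lp_p = logprior(rates, mp)
        if np.log(rng.uniform()) < lp_p - lp + np.log(mp / m):
            m, lp = mp, lp_p
        # -- dimension move: reassign one position
        pos = int(rng.integers(n_pos))
        cur = assign[pos]
        classes = sorted(set(a for a in assign if a != ZERO))
        options = [c for c in classes if c != cur] + ["NEW"]
        if allow_zero and cur != ZERO:
            options.append(ZERO)
        if options:
            choice = options[int(rng.integers(len(options)))]
            new_assign = list(assign)
            new_rates = dict(rates)
            if choice == "NEW":
                new_cls = f"c{next_class}"
                new_assign[pos] = new_cls
                new_rates[new_cls] = rng.exponential(m)   # prior draw: cancels
            elif choice == ZERO:
                new_assign[pos] = ZERO
            else:
                new_assign[pos] = choice
            # drop emptied classes
            used = set(a for a in new_assign if a != ZERO)
            for c in list(new_rates):
                if c not in used:
                    del new_rates[c]
            # reverse-move option count for Hastings ratio
            rev_classes = sorted(used)
            rev_options = [c for c in rev_classes if c != new_assign[pos]] + ["NEW"]
            if allow_zero and new_assign[pos] != ZERO:
                rev_options.append(ZERO)
            ll_p = loglik(new_assign, new_rates)
            lp_p = logprior(new_rates, m)
            # exponential prior of created/destroyed class cancels against
            # its proposal; remaining prior ratio handled by logprior diff
            extra = 0.0
            if choice == "NEW":
                extra += np.log(m) + new_rates[new_assign[pos]] / m
            if cur not in new_rates and cur != ZERO and cur in rates:
                extra -= np.log(m) + rates[cur] / m
            log_alpha = (ll_p - ll + lp_p - lp + extra
                         + np.log(len(options)) - np.log(len(rev_options)))
            if np.log(rng.uniform()) < log_alpha:
                assign, rates, ll, lp = new_assign, new_rates, ll_p, lp_p
                if choice == "NEW":
                    next_class += 1
        if it < config.burn_in and (it + 1) % 50 == 0 and tot_n:
            step *= math.exp(np.clip(acc_n / tot_n - 0.3, -0.5, 0.5))
            step = float(np.clip(step, 0.01, 5.0))
            acc_n = tot_n = 0
        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0 \
                and kept < n_keep:
            model_ids.append(_canonical_model_id(assign))
            lls[kept] = ll
            vals = list(rates.values())
            mean_rate[kept] = float(np.mean(vals)) if vals else 0.0
            kept += 1
    return Chain(mean_rate[:kept, None], ["mean_rate"], lls[:kept], config,
                 model_ids=model_ids)


def model_frequencies(chain: Chain) -> dict[str, float]:
    """Posterior visit fractions of RJ model ids, most frequent first."""
    if not chain.model_ids:
        raise ValueError("chain has no model-id trace")
    import collections

    counts = collections.Counter(chain.model_ids)
    total = sum(counts.values())
    return {mid: c / total for mid, c in counts.most_common()}


# ---- diagnostics ---------------------------------------------------------


def _ess_ips(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1))
    acf /= acf[0]
    # sum consecutive pairs while positive (Geyer initial positive sequence)
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    tau = 1.0 + 2.0 * s
    return float(n / max(tau, 1.0))


def chain_diagnostics(chains) -> ChainDiagnostics:
    """ESS (initial positive sequence) and split-Rhat across chains.

    Accepts one Chain or a list; with a single chain the split halves stand
    in for multiple chains (split-Rhat), reported as None when fewer than 50
    retained draws are available.
    """
    if isinstance(chains, Chain):
        chains = [chains]
    draws = [c.draws for c in chains]
    n_params = draws[0].shape[1]
    names = chains[0].param_names
    ess = np.array([sum(_ess_ips(d[:, j]) for d in draws)
                    for j in range(n_params)])
    n_min = min(d.shape[0] for d in draws)
    if n_min < 50:
        return ChainDiagnostics(ess, None, True, names)
    # multiple chains: between-chain Gelman-Rubin on whole chains;
    # single chain: split halves stand in for separate chains
    if len(draws) >= 2:
        n_use = min(d.shape[0] for d in draws)
        seqs_all = [d[:n_use] for d in draws]
    else:
        h = draws[0].shape[0] // 2
        seqs_all = [draws[0][:h], draws[0][h: 2 * h]]
    rhat = np.empty(n_params)
    for j in range(n_params):
        seqs = np.array([s[:, j] for s in seqs_all])
        _, n = seqs.shape
        means = seqs.mean(axis=1)
        w = seqs.var(axis=1, ddof=1).mean()
        b = n * means.var(ddof=1)
        if w <= 0:
            rhat[j] = 1.0
        else:
            var_plus = (n - 1) / n * w + b / n
            rhat[j] = max(1.0, math.sqrt(var_plus / w))
    # harmonic-mean stability heuristic (warning-only): compare the harmonic
    # mean estimator over chain halves
    stable = True
    for c in chains:
        ll = c.loglik
        h = ll.size // 2
        if h >= 25:
            hm1 = -np.log(np.mean(np.exp(-(ll[:h] - ll[:h].max())))) + ll[:h].max()
            hm2 = -np.log(np.mean(np.exp(-(ll[h:] - ll[h:].max())))) + ll[h:].max()
            if abs(hm1 - hm2) > 5.0:
                stable = False
    return ChainDiagnostics(ess, rhat, stable, names)
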