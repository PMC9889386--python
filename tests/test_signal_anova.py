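import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from sociophylo import ctmc, signal_anova as sa, synthetic_data as sd
from sociophylo.treeio import PhyloTree


def star_tree(n, length=1.0):
    parent = np.array([n] * n + [-1])
    blen = np.array([length] * n + [0.0])
    return PhyloTree(parent, blen, [f"t{i}" for i in range(n)])


class TestLambdaContinuous:
    def test_bm_data_high_lambda(self, yule300):
        hits = 0
        for s in range(10):
            df, _ = sd.simulate_continuous_bm(yule300, 1.0, 1.0, seed=40 + s)
            fit = sa.lambda_continuous(yule300, df["rep0"])
            hits += fit.lam >= 0.9
        assert hits >= 9

    def test_permuted_data_low_lambda(self, yule300):
        low, insignificant = 0, 0
        rng = np.random.default_rng(0)
        for s in range(10):
            df, _ = sd.simulate_continuous_bm(yule300, 1.0, 1.0, seed=60 + s)
            y = pd.Series(rng.permutation(df["rep0"].to_numpy()),
                          index=yule300.tip_labels)
            fit = sa.lambda_continuous(yule300, y)
            low += fit.lam < 0.2
            insignificant += fit.lr_pvalue > 0.05
        assert low >= 9 and insignificant >= 9

    def test_loglik_ordering_invariant(self, yule300):
        df, _ = sd.simulate_continuous_bm(yule300, 1.0, 0.6, seed=70)
        fit = sa.lambda_continuous(yule300, df["rep0"])
        assert fit.loglik_lambda >= fit.loglik_zero - 1e-9
        assert 0.0 <= fit.lam <= 1.0

    def test_star_tree_flat_flag(self):
        t = star_tree(40)
        rng = np.random.default_rng(1)
        y = pd.Series(rng.standard_normal(40), index=t.tip_labels)
        fit = sa.lambda_continuous(t, y)
        assert fit.flat_likelihood

    def test_constant_trait_rejected(self, yule300):
        y = pd.Series(1.0, index=yule300.tip_labels)
        with pytest.raises(ValueError):
            sa.lambda_continuous(yule300, y)


class TestLambdaDiscrete:
    def test_er_data_high_lambda(self, yule300):
        m = ctmc.build_rate_matrix("ER", (0, 1), 0.5)
        trait, _ = sd.simulate_discrete_trait(yule300, m, seed=80)
        fit = sa.lambda_discrete(yule300, trait)
        assert fit.lam >= 0.8

    def test_iid_data_null_recovery(self, yule300):
        """iid tip states carry no signal: lambda-hat at 0 or the LR test
        insignificant in nearly all replicates."""
        ok = 0
        for seed in range(6):
            rng = np.random.default_rng(seed)
            trait = pd.Series(rng.integers(0, 2, yule300.n_tips),
                              index=yule300.tip_labels)
            fit = sa.lambda_discrete(yule300, trait)
            ok += (fit.lam < 0.3) or (fit.lr_pvalue > 0.05)
        assert ok >= 5

    def test_zero_lambda_equals_star_tree_likelihood(self, yule100):
        from sociophylo.treeio import lambda_transform

        m = ctmc.build_rate_matrix("ER", (0, 1), 0.5)
        trait, _ = sd.simulate_discrete_trait(yule100, m, seed=81)
        star = lambda_transform(yule100, 0.0)
        fit_star = ctmc.fit_ml_discrete(star, trait, "ER", n_restarts=3)
        fit0 = sa.lambda_discrete(yule100, trait)
        assert fit0.loglik_zero == pytest.approx(fit_star.loglik, abs=1e-4)


class TestPhyloAnova:
    def test_star_tree_matches_plain_anova(self):
        """On a star tree the simulated null is iid normal, so the p-value
        agrees with classical one-way ANOVA within MC error."""
        t = star_tree(60)
        rng = np.random.default_rng(5)
        y = pd.Series(rng.standard_normal(60), index=t.tip_labels)
        groups = pd.Series(rng.choice(list("abc"), 60), index=t.tip_labels)
        y[groups == "a"] += 1.0
        res = sa.phylo_anova(t, y, groups, nsim=4000, seed=6)
        f_cl, p_cl = scipy.stats.f_oneway(*[y[groups == g]
                                            for g in "abc"])
        assert res.f_observed == pytest.approx(f_cl, rel=1e-9)
        assert res.p_value == pytest.approx(p_cl, abs=0.02)

    def test_identical_groups_f_zero(self, yule100):
        y = pd.Series(np.repeat([2.0], 100), index=yule100.tip_labels)
        y.iloc[:50] = 1.0
        groups = pd.Series(["a", "b"] * 50, index=yule100.tip_labels)
        y[:] = 3.0
        res = sa.phylo_anova(yule100, y + np.random.default_rng(7)
                             .standard_normal(100) * 1e-9, groups,
                             nsim=200, seed=8)
        assert res.p_value > 0.5

    def test_planted_shift_detected(self, yule100):
        rng = np.random.default_rng(9)
        hits = 0
        groups = pd.Series(rng.choice(["a", "b"], 100),
                           index=yule100.tip_labels)
        for s in range(10):
            df, _ = sd.simulate_continuous_bm(yule100, 1.0, 1.0, seed=90 + s)
            y = df["rep0"].copy()
            y[groups == "b"] += 3.0 * y.std()
            res = sa.phylo_anova(yule100, y, groups, nsim=300, seed=s)
            hits += res.p_value < 0.05
        assert hits >= 9

    def test_singleton_group_rejected(self, yule100):
        y = pd.Series(np.arange(100.0), index=yule100.tip_labels)
        groups = pd.Series(["a"] * 99 + ["b"], index=yule100.tip_labels)
        with pytest.raises(ValueError):
            sa.phylo_anova(yule100, y, groups, nsim=200, seed=0)

    def test_adjusted_ge_raw(self, yule100):
        rng = np.random.default_rng(11)
        df, _ = sd.simulate_continuous_bm(yule100, 1.0, 1.0, seed=95)
        groups = pd.Series(rng.choice(list("abcd"), 100),
                           index=yule100.tip_labels)
        res = sa.phylo_anova(yule100, df["rep0"], groups, nsim=300, seed=12)
        assert (res.pairwise["p_hommel"] >= res.pairwise["p_raw"] - 1e-12).all()


def _hommel_brute_force(p):
    """Closed-testing adjustment by enumerating all intersection hypotheses
    with the Simes local test (m <= 5)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    adj = np.zeros(m)
    idx = list(range(m))
    for i in idx:
        worst = 0.0
        for r in range(1, m + 1):
            for subset in itertools.combinations(idx, r):
                if i not in subset:
                    continue
                ps = np.sort(p[list(subset)])
                simes = min((len(subset) / (k + 1)) * ps[k]
                            for k in range(len(subset)))
                worst = max(worst, min(simes, 1.0))
        adj[i] = worst
    return adj


class TestHommel:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sa.hommel_adjust([0.04]), [0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(sa.hommel_adjust([1.0, 1.0, 1.0]),
                                   [1.0, 1.0, 1.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_closed_testing(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 6))
        p = np.round(rng.uniform(0.001, 0.8, m), 4)
        np.testing.assert_allclose(sa.hommel_adjust(p),
                                   _hommel_brute_force(p), atol=1e-10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sa.hommel_adjust([0.5, 1.2])
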