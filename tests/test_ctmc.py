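import itertools

import numpy as np
import pytest
import scipy.linalg

from sociophylo import ctmc, synthetic_data as sd
from sociophylo.treeio import read_newick


class TestBuildRateMatrix:
    def test_er_structure(self):
        m = ctmc.build_rate_matrix("ER", (0, 1, 2), 0.5)
        Q = m.q_matrix()
        off = Q[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5)
        np.testing.assert_allclose(np.diag(Q), -1.0)
        assert m.n_free == 1

    def test_ic_forbids_solitary_group(self):
        m = ctmc.build_rate_matrix("IC", ("solitary", "pair-living",
                                          "group-living"), [0.1, 0.2, 0.3, 0.4])
        Q = m.q_matrix()
        assert Q[0, 2] == 0.0 and Q[2, 0] == 0.0
        assert m.n_free == 4

    def test_ard_parameter_count(self):
        m = ctmc.build_rate_matrix("ARD", (0, 1, 2), np.arange(1, 7) / 10)
        assert m.n_free == 6
        np.testing.assert_allclose(m.q_matrix().sum(axis=1), 0.0, atol=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ctmc.build_rate_matrix("ER", (0, 1), -0.5)

    def test_ic_needs_three_states(self):
        with pytest.raises(ValueError):
            ctmc.build_rate_matrix("IC", (0, 1), [0.1])


class TestTransitionMatrices:
    @pytest.mark.parametrize("seed", range(5))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        Q = rng.exponential(1.0, (k, k))
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        t = rng.exponential(1.0, 20)
        P = ctmc.transition_matrices(Q, t)
        np.testing.assert_allclose(P.sum(axis=2), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_matches_expm(self):
        rng = np.random.default_rng(1)
        Q = rng.exponential(1.0, (3, 3))
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        t = np.array([0.0, 0.3, 2.0])
        P = ctmc.transition_matrices(Q, t)
        for i, ti in enumerate(t):
            np.testing.assert_allclose(P[i], scipy.linalg.expm(Q * ti),
                                       atol=1e-9)


def _brute_force_loglik(tree, states_by_tip, Q, root_dist):
    """Enumerate all internal-node state assignments (trees <= 6 tips)."""
    k = Q.shape[0]
    n = tree.n_nodes
    internal = [i for i in range(n) if i >= tree.n_tips]
    P = {}
    for node in range(n):
        if tree.parent[node] >= 0:
            P[node] = scipy.linalg.expm(Q * tree.blen[node])
    total = 0.0
    tips = {i: states_by_tip[tree.tip_labels[i]] for i in range(tree.n_tips)}
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        prob = root_dist[amap[tree.root]]
        for node in range(n):
            p = tree.parent[node]
            if p < 0:
                continue
            if node < tree.n_tips:
                prob *= sum(P[node][amap[p], s] for s in tips[node])
            else:
                prob *= P[node][amap[p], amap[node]]
        total += prob
    return np.log(total)


class TestPruningLikelihood:
    def test_zero_length_branches(self):
        t = read_newick("(A:0,B:0):0;")
        m = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
        ll = ctmc.pruning_loglik(t, {"A": 0, "B": 0}, m)
        assert ll == pytest.approx(-np.log(2))

    def test_two_tip_closed_form(self):
        # P00(t) = 1/2 + 1/2 exp(-2t) for the symmetric 2-state chain
        t = read_newick("(A:0.5,B:0.5):0;")
        m = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
        ll = ctmc.pruning_loglik(t, {"A": 0, "B": 0}, m)
        p00 = 0.5 + 0.5 * np.exp(-1.0)
        p10 = 0.5 - 0.5 * np.exp(-1.0)
        expected = 0.5 * (p00**2 + p10**2)
        assert ll == pytest.approx(np.log(expected), abs=1e-12)
        assert expected == pytest.approx(0.2838, abs=1e-4)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 7))
        tree = sd.simulate_yule_tree(n_tips, 1.0, seed=seed + 100)
        k = int(rng.integers(2, 4))
        Q = rng.exponential(0.7, (k, k))
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        states = {}
        for lab in tree.tip_labels:
            if rng.random() < 0.2:
                size = int(rng.integers(1, k + 1))
                states[lab] = set(rng.choice(k, size=size, replace=False)
                                  .tolist())
            else:
                states[lab] = {int(rng.integers(k))}
        root = np.full(k, 1.0 / k)
        ll = ctmc.pruning_loglik(tree, {l: s for l, s in states.items()}, Q,
                                 root)
        bf = _brute_force_loglik(tree, states, Q, root)
        assert ll == pytest.approx(bf, abs=1e-10)

    def test_fully_ambiguous_tip_equals_pruned(self, yule100):
        from sociophylo.treeio import prune_to

        m = ctmc.build_rate_matrix("ER", (0, 1), 0.7)
        trait, _ = sd.simulate_discrete_trait(yule100, m, seed=9)
        trait = trait.to_dict()
        dropped = yule100.tip_labels[0]
        trait_amb = dict(trait)
        trait_amb[dropped] = {0, 1}
        ll_amb = ctmc.pruning_loglik(yule100, trait_amb, m)
        sub = prune_to(yule100, [t for t in yule100.tip_labels
                                 if t != dropped])
        ll_pruned = ctmc.pruning_loglik(sub, trait, m)
        assert ll_amb == pytest.approx(ll_pruned, abs=1e-9)

    def test_missing_tip_raises(self, small_tree):
        m = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
        with pytest.raises(KeyError):
            ctmc.pruning_loglik(small_tree, {"A": 0, "B": 1}, m)

    def test_rescaling_invariance(self, yule100):
        """Multiplying branches by c and dividing rates by c is a no-op."""
        from sociophylo.treeio import scale_branches_to_mean

        m = ctmc.build_rate_matrix("ER", (0, 1), 0.8)
        trait, _ = sd.simulate_discrete_trait(yule100, m, seed=4)
        ll0 = ctmc.pruning_loglik(yule100, trait, m)
        c = 5.0
        scaled = yule100.copy()
        scaled.blen = yule100.blen * c
        m2 = ctmc.build_rate_matrix("ER", (0, 1), 0.8 / c)
        ll1 = ctmc.pruning_loglik(scaled, trait, m2)
        assert ll0 == pytest.approx(ll1, abs=1e-9)


class TestKernelPaths:
    def test_numba_and_numpy_paths_agree(self, yule100):
        import sociophylo.ctmc as C

        m = ctmc.build_rate_matrix("ARD", (0, 1, 2), np.arange(1, 7) / 5)
        trait, _ = sd.simulate_discrete_trait(yule100, m, seed=30)
        part = ctmc.tip_partials(yule100, trait, 3)
        had = C._HAVE_NUMBA
        try:
            C._HAVE_NUMBA = False
            ll_np = ctmc.pruning_loglik(yule100, part, m)
        finally:
            C._HAVE_NUMBA = had
        ll = ctmc.pruning_loglik(yule100, part, m)
        assert ll == pytest.approx(ll_np, abs=1e-9)


class TestFitML:
    def test_er_recovery_within_2se(self):
        tree = sd.simulate_yule_tree(1000, 1.0, seed=20)
        m = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
        trait, _ = sd.simulate_discrete_trait(tree, m, seed=21)
        fit = ctmc.fit_ml_discrete(tree, trait, "ER", n_restarts=4)
        assert fit.converged
        assert abs(fit.rates[0] - 1.0) < 2 * fit.se[0]

    def test_constant_trait_flagged(self, yule100):
        trait = {lab: 0 for lab in yule100.tip_labels}
        fit = ctmc.fit_ml_discrete(yule100, trait, "ER", states=(0, 1),
                                   n_restarts=2)
        assert fit.boundary

    def test_nested_models_loglik_order(self, yule100):
        m = ctmc.build_rate_matrix("ER", (0, 1, 2), 0.5)
        trait, _ = sd.simulate_discrete_trait(yule100, m, seed=22)
        f_er = ctmc.fit_ml_discrete(yule100, trait, "ER", n_restarts=3)
        f_ard = ctmc.fit_ml_discrete(yule100, trait, "ARD", n_restarts=3)
        assert f_ard.loglik >= f_er.loglik - 1e-6
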