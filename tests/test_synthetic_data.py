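import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.stats

from sociophylo import ctmc, synthetic_data as sd
from sociophylo.treeio import phylo_covariance


class TestYuleTree:
    def test_two_tips_ultrametric(self):
        t = sd.simulate_yule_tree(2, 1.0, seed=7)
        d = t.tip_depths()
        assert d[0] == pytest.approx(d[1])

    def test_internal_node_count(self):
        t = sd.simulate_yule_tree(100, 1.0, seed=1)
        assert t.n_nodes - t.n_tips == 99
        assert t.is_binary() and t.is_ultrametric()

    def test_determinism(self):
        a = sd.simulate_yule_tree(50, 1.0, seed=3)
        b = sd.simulate_yule_tree(50, 1.0, seed=3)
        np.testing.assert_array_equal(a.parent, b.parent)
        np.testing.assert_array_equal(a.blen, b.blen)

    def test_waiting_times_match_yule_oracle(self):
        """Inter-speciation waiting times are Exp(n*b): compare the total
        depth distribution against a direct brute-force Yule simulation."""
        n, b = 20, 2.0
        depths = [sd.simulate_yule_tree(n, b, seed=s).tip_depths()[0]
                  for s in range(300)]
        rng = np.random.default_rng(999)
        oracle = [sum(rng.exponential(1.0 / (b * k)) for k in range(2, n + 1))
                  for _ in range(300)]
        ks = scipy.stats.ks_2samp(depths, oracle)
        assert ks.pvalue > 0.01

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            sd.simulate_yule_tree(1, 1.0, 0)
        with pytest.raises(ValueError):
            sd.simulate_yule_tree(5, -1.0, 0)


class TestDiscreteTrait:
    def test_zero_rates_freeze_root_state(self, yule100):
        m = ctmc.build_rate_matrix("ER", (0, 1, 2), 0.0)
        col, _ = sd.simulate_discrete_trait(yule100, m, [0, 0, 1], seed=2)
        assert (col == 2).all()

    def test_fast_chain_reaches_stationarity(self):
        t = sd.simulate_yule_tree(500, 1.0, seed=4)
        m = ctmc.build_rate_matrix("ER", (0, 1), 100.0)
        col, _ = sd.simulate_discrete_trait(t, m, seed=5)
        freq = (col == 0).mean()
        assert 0.4 < freq < 0.6

    def test_single_branch_matches_matrix_exponential(self):
        """Empirical transition frequencies over many draws agree with
        exp(Qt) rows within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(0)
        Q = np.array([[-1.0, 0.6, 0.4], [0.2, -0.5, 0.3], [0.7, 0.3, -1.0]])
        t = 0.8
        P = scipy.linalg.expm(Q * t)
        n = 100_000
        draws = np.array([sd._gillespie_branch(0, Q, t, rng)
                          for _ in range(n)])
        for s in range(3):
            p_hat = (draws == s).mean()
            se = np.sqrt(P[0, s] * (1 - P[0, s]) / n)
            assert abs(p_hat - P[0, s]) < 3 * se + 1e-12

    def test_bad_root_distribution(self, yule100):
        m = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
        with pytest.raises(ValueError):
            sd.simulate_discrete_trait(yule100, m, [0.7, 0.7], seed=0)


class TestBinaryPair:
    def test_unreachable_state(self, yule100):
        # gain of y only when x=1; all reverse/loss rates off; root (0,0)
        rates = [0.0, 0.5, 0.0, 0.0, 0.0, 2.0, 0.0, 0.0]
        from sociophylo.correlated import build_pair_model

        m = build_pair_model("dependent", rates)
        m.root_rule = np.array([1.0, 0, 0, 0])
        df, _ = sd.simulate_binary_pair(yule100, m, seed=3)
        # (0,1) unreachable: y can only switch on after x
        assert not ((df["x"] == 0) & (df["y"] == 1)).any()

    def test_truth_records_kind(self, yule100):
        from sociophylo.correlated import build_pair_model

        dep = build_pair_model("dependent", [0.2, 0.5, 2, 0.5, 0.5, 2, 0.5, 0.2])
        ind = build_pair_model("independent", [0.5, 0.5, 0.5, 0.5])
        _, t1 = sd.simulate_binary_pair(yule100, dep, seed=0)
        _, t2 = sd.simulate_binary_pair(yule100, ind, seed=0)
        assert t1.parameters["kind"] == "dependent"
        assert t2.parameters["kind"] == "independent"

    def test_independent_pair_no_association(self):
        """Across replicates the tip-level association of independently
        evolving traits is centred at zero."""
        t = sd.simulate_yule_tree(60, 1.0, seed=8)
        from sociophylo.correlated import build_pair_model

        ind = build_pair_model("independent", [1.0, 1.0, 1.0, 1.0])
        phis = []
        for s in range(100):
            df, _ = sd.simulate_binary_pair(t, ind, seed=s)
            if df["x"].nunique() < 2 or df["y"].nunique() < 2:
                continue
            phis.append(np.corrcoef(df["x"], df["y"])[0, 1])
        m = np.mean(phis)
        assert abs(m) < 3 * np.std(phis) / np.sqrt(len(phis)) + 0.02

    def test_dual_transition_rejected(self, yule100):
        m = ctmc.build_rate_matrix("ARD", tuple(range(4)), np.full(12, 0.5))
        with pytest.raises(ValueError):
            sd.simulate_binary_pair(yule100, m, seed=0)


class TestContinuousBM:
    def test_lambda_zero_independent(self):
        t = sd.simulate_yule_tree(50, 1.0, seed=9)
        df, _ = sd.simulate_continuous_bm(t, 1.0, 0.0, seed=10, size=400)
        X = df.to_numpy()
        c = np.corrcoef(X)
        off = c[~np.eye(50, dtype=bool)]
        assert np.abs(off).mean() < 0.1

    def test_lambda_one_covariance_matches_tree(self):
        t = sd.simulate_yule_tree(25, 1.0, seed=11)
        df, _ = sd.simulate_continuous_bm(t, 1.0, 1.0, seed=12, size=1500)
        S = np.cov(df.to_numpy())
        C = phylo_covariance(t)
        assert np.abs(S - C).max() / C.max() < 0.25

    def test_invalid_lambda(self, yule100):
        with pytest.raises(ValueError):
            sd.simulate_continuous_bm(yule100, 1.0, 1.5, seed=0)


class TestExpressionPanel:
    def test_truth_lists_planted_genes(self, yule100):
        tr = pd.DataFrame({"x": np.random.default_rng(0).standard_normal(100)},
                          index=yule100.tip_labels)
        panel = sd.simulate_expression_panel(yule100, tr, 50,
                                             {"x": (0.2, 2.0)}, (1.0, 1.0),
                                             seed=1)
        planted = panel.truth.parameters["planted"]["x"]
        assert len(planted) == 10
        betas = np.array(panel.truth.parameters["betas"]["x"])
        assert (np.abs(betas) > 0).sum() == 10

    def test_rows_match_tree_tips(self, yule100):
        tr = pd.DataFrame({"x": np.zeros(100)}, index=yule100.tip_labels)
        panel = sd.simulate_expression_panel(yule100, tr, 10, {}, (1, 1),
                                             seed=2)
        assert list(panel.values.index) == list(yule100.tip_labels)

    def test_bad_variances(self, yule100):
        tr = pd.DataFrame({"x": np.zeros(100)}, index=yule100.tip_labels)
        with pytest.raises(ValueError):
            sd.simulate_expression_panel(yule100, tr, 10, {}, (1.0, 0.0),
                                         seed=0)


class TestCountsAndSets:
    def test_column_sums_near_library_sizes(self):
        cm, gl, _ = sd.simulate_count_matrix(3000, 4, [1e6] * 4, 0.05, seed=3)
        totals = cm.sum(axis=0)
        assert ((totals - 1e6).abs() / 1e6 < 0.2).all()
        assert gl.between(200, 10000).all()

    def test_dispersion_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_count_matrix(10, 2, None, -0.1, seed=0)

    def test_planted_set_scores_shifted(self):
        sets, scores, truth = sd.make_gene_sets(500, 5, (10, 30),
                                                [("set0001", 2.0)], seed=4)
        inside = scores.loc[sets["set0001"]].mean()
        outside = scores.drop(sets["set0001"]).mean()
        assert inside - outside > 1.0

    def test_size_range_validated(self):
        with pytest.raises(ValueError):
            sd.make_gene_sets(100, 3, (1, 10), seed=0)


class TestMissingness:
    @pytest.fixture()
    def table(self, yule100):
        rng = np.random.default_rng(6)
        return pd.DataFrame({
            "body_mass": rng.lognormal(8, 2, 100),
            "value": rng.standard_normal(100),
        }, index=yule100.tip_labels)

    def test_exact_count(self, table, yule100):
        out, truth_vals, _ = sd.inject_missingness(table, "value", "MCAR",
                                                   0.10, seed=1)
        assert out["value"].isna().sum() == 10
        assert len(truth_vals) == 10

    def test_mar_bm_mass_dependent(self, table, yule100):
        """Mask correlates with body-mass rank by construction."""
        corrs = []
        for s in range(30):
            out, _, _ = sd.inject_missingness(table, "value", "MAR-BM", 0.3,
                                              seed=s)
            mask = out["value"].isna().astype(float)
            corrs.append(scipy.stats.pointbiserialr(
                mask, np.log(table["body_mass"]))[0])
        assert np.mean(corrs) > 0.2

    def test_mcar_clade_independent(self, table, yule100):
        """MCAR masked counts inside a clade follow the hypergeometric
        expectation (mask independent of clade membership)."""
        ch = yule100.children()
        # find a mid-sized clade (20-60 tips)
        clade = None
        for node in range(yule100.n_tips, yule100.n_nodes):
            stack, tips = [node], []
            while stack:
                u = stack.pop()
                if u < yule100.n_tips:
                    tips.append(yule100.tip_labels[u])
                else:
                    stack.extend(ch[u])
            if 20 <= len(tips) <= 60:
                clade = set(tips)
                break
        assert clade is not None
        n, K, n_mask = 100, len(clade), 30
        counts = []
        for s in range(60):
            out, _, _ = sd.inject_missingness(table, "value", "MCAR", 0.3,
                                              seed=s)
            masked = set(out.index[out["value"].isna()])
            counts.append(len(masked & clade))
        expect = n_mask * K / n
        var = n_mask * (K / n) * (1 - K / n) * (n - n_mask) / (n - 1)
        se_mean = np.sqrt(var / len(counts))
        assert abs(np.mean(counts) - expect) < 4 * se_mean

    def test_fraction_validation(self, table):
        with pytest.raises(ValueError):
            sd.inject_missingness(table, "value", "MCAR", 1.5, seed=0)

    def test_mar_phy_needs_tree(self, table):
        with pytest.raises(ValueError):
            sd.inject_missingness(table, "value", "MAR-Phy", 0.2, seed=0)

    def test_generator_determinism(self, table):
        a = sd.inject_missingness(table, "value", "MCAR", 0.2, seed=5)[0]
        b = sd.inject_missingness(table, "value", "MCAR", 0.2, seed=5)[0]
        pd.testing.assert_frame_equal(a, b)
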