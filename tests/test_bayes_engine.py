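import numpy as np
import pytest

from sociophylo import bayes_engine as be, ctmc, synthetic_data as sd


@pytest.fixture(scope="module")
def er_data():
    tree = sd.simulate_yule_tree(100, 1.0, seed=5)
    model = ctmc.build_rate_matrix("ER", (0, 1), 1.0)
    trait, _ = sd.simulate_discrete_trait(tree, model, seed=6)
    return tree, model, trait


class TestLogBayesFactor:
    def test_printed_table_values(self):
        # Log BF = 2 x (logML complex - logML simple)
        c = be.log_bayes_factor(-555.27, -571.95)
        assert c.log_bf == pytest.approx(33.36, abs=0.01)
        assert c.category == "very strong"
        c2 = be.log_bayes_factor(-346.26, -361.43)
        assert c2.log_bf == pytest.approx(30.34, abs=0.01)

    def test_equal_inputs_favor_simple(self):
        c = be.log_bayes_factor(-10.0, -10.0)
        assert c.log_bf == 0.0 and c.favored == "simple"

    @pytest.mark.parametrize("bf,cat", [(1.0, "simple"), (3.0, "positive"),
                                        (7.0, "strong"), (15.0, "very strong")])
    def test_categories(self, bf, cat):
        assert be.evidence_category(bf) == cat

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            be.log_bayes_factor(float("nan"), 0.0)


class TestRunMcmc:
    def test_prior_recovery_with_empty_data(self, er_data):
        """With a flat likelihood the rate posterior is its prior: an
        exponential whose mean is U(0,2)-distributed, so E[rate] = 1."""
        tree, model, _ = er_data
        amb = {lab: {0, 1} for lab in tree.tip_labels}
        cfg = be.EngineConfig(iterations=6000, burn_in=1500, thinning=3,
                              seed=1)
        chain = be.run_mcmc(tree, amb, model, cfg)
        assert chain.draws.mean() == pytest.approx(1.0, abs=0.15)

    def test_posterior_covers_truth(self, er_data):
        tree, model, trait = er_data
        cfg = be.EngineConfig(iterations=6000, burn_in=1500, thinning=3,
                              seed=2)
        chain = be.run_mcmc(tree, trait, model, cfg)
        post_mean, post_sd = chain.draws.mean(), chain.draws.std()
        assert abs(post_mean - 1.0) < 2.5 * post_sd

    def test_two_seeds_converge(self, er_data):
        tree, model, trait = er_data
        chains = [be.run_mcmc(tree, trait, model,
                              be.EngineConfig(iterations=4000, burn_in=1000,
                                              thinning=2, seed=s))
                  for s in (3, 4)]
        d = be.chain_diagnostics(chains)
        assert (d.rhat < 1.1).all()

    def test_bad_hyperprior(self, er_data):
        tree, model, trait = er_data
        with pytest.raises(ValueError):
            be.run_mcmc(tree, trait, model, hyperprior=(2.0, 1.0))


class TestSteppingStone:
    def _toy(self, seed=42, n=20, mu=0.5):
        rng = np.random.default_rng(seed)
        y = rng.normal(mu, 1.0, size=n)
        post_var = 1.0 / (n + 1)
        logml = (-0.5 * n * np.log(2 * np.pi) - 0.5 * (y ** 2).sum()
                 + 0.5 * (y.sum() ** 2) * post_var + 0.5 * np.log(post_var))

        def loglik(m):
            return float(-0.5 * n * np.log(2 * np.pi)
                         - 0.5 * ((y - m) ** 2).sum())

        def sample_prior(rng):
            return rng.normal()

        def mh(m, ll, beta, rng):
            prop = m + 0.8 * rng.standard_normal()
            llp = loglik(prop)
            if np.log(rng.uniform()) < beta * (llp - ll) \
                    - 0.5 * prop ** 2 + 0.5 * m ** 2:
                return prop, llp
            return m, ll

        return loglik, sample_prior, mh, logml

    def test_conjugate_normal_oracle(self):
        """Estimate matches the closed-form marginal likelihood within
        3 MC standard deviations over 20 seeds (50 stones x 1000 iters)."""
        loglik, sample_prior, mh, logml = self._toy()
        ests = np.array([be.stepping_stone_generic(loglik, sample_prior, mh,
                                                   50, 1000, seed=s)
                         for s in range(20)])
        assert abs(ests.mean() - logml) < 3 * ests.std() / np.sqrt(20) + 0.01
        assert np.var(ests) < 0.03   # repeat-run stability criterion

    def test_flat_likelihood_gives_zero(self):
        _, sample_prior, _, _ = self._toy()

        def const_ll(m):
            return 0.0

        def mh(m, ll, beta, rng):
            prop = m + 0.8 * rng.standard_normal()
            if np.log(rng.uniform()) < -0.5 * prop ** 2 + 0.5 * m ** 2:
                return prop, 0.0
            return m, ll

        z = be.stepping_stone_generic(const_ll, sample_prior, mh, 20, 300,
                                      seed=1)
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_variance_shrinks_with_more_stones(self):
        loglik, sample_prior, mh, _ = self._toy()
        few = np.array([be.stepping_stone_generic(loglik, sample_prior, mh,
                                                  3, 300, seed=s)
                        for s in range(12)])
        many = np.array([be.stepping_stone_generic(loglik, sample_prior, mh,
                                                   30, 300, seed=s)
                         for s in range(12)])
        assert many.std() < few.std()

    def test_tree_model_needs_two_stones(self, er_data):
        tree, model, trait = er_data
        with pytest.raises(ValueError):
            be.stepping_stone_logml(tree, trait, model, stones=1,
                                    iterations_per_stone=10)


class TestRJMCMC:
    def test_er_data_recovers_shared_class(self, er_data):
        tree, _, trait = er_data
        cfg = be.EngineConfig(iterations=4000, burn_in=1000, thinning=2,
                              seed=7)
        chain = be.run_rjmcmc(tree, trait, (0, 1), cfg)
        freqs = be.model_frequencies(chain)
        top = next(iter(freqs))
        assert top == "AA"           # both positions share one rate class
        assert sum(freqs.values()) == pytest.approx(1.0)

    def test_forbidden_transition_lands_in_zero_class(self):
        tree = sd.simulate_yule_tree(200, 1.0, seed=8)
        # 0->1 forbidden; start at 1 so the data show only 1->0 moves
        model = ctmc.build_rate_matrix(
            "custom", (0, 1), {"c": 1.5}, zero_pairs=[(0, 1)])
        trait, _ = sd.simulate_discrete_trait(tree, model, [0.0, 1.0], seed=9)
        cfg = be.EngineConfig(iterations=6000, burn_in=1500, thinning=2,
                              seed=10)
        chain = be.run_rjmcmc(tree, trait, (0, 1), cfg)
        freqs = be.model_frequencies(chain)
        top = next(iter(freqs))
        assert top[0] == "Z"         # position (0,1) assigned rate zero


class TestDiagnostics:
    def test_iid_normal_ess(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        ess = be._ess_ips(x)
        assert 800 <= ess <= 1200

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal((500, 1))
        cfg = be.EngineConfig()
        c = be.Chain(draws, ["r"], np.zeros(500), cfg)
        d = be.chain_diagnostics([c, be.Chain(draws.copy(), ["r"],
                                              np.zeros(500), cfg)])
        assert d.rhat[0] == pytest.approx(1.0, abs=1e-6)

    def test_ar1_ess_matches_closed_form(self):
        rho = 0.9
        rng = np.random.default_rng(2)
        n = 20000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        ess = be._ess_ips(x)
        expected = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.3)

    def test_short_chain_no_rhat(self):
        cfg = be.EngineConfig()
        c = be.Chain(np.random.default_rng(3).standard_normal((30, 1)),
                     ["r"], np.zeros(30), cfg)
        assert be.chain_diagnostics(c).rhat is None

    def test_ess_agrees_with_arviz(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2000)
        ours = be._ess_ips(x)
        theirs = float(arviz.ess(x))
        assert abs(ours - theirs) / theirs < 0.25
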