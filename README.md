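# sociophylo

Phylogenetic comparative analysis of social organization and longevity in
mammals — discrete-trait Markov models with Bayesian model comparison,
correlated-evolution tests, phylogenetic signal and ANOVA, phylogenetic
mixed models for trait and gene-expression regression, SUMSTAT gene-set
enrichment, RNA-seq count normalization, and Brownian-motion trait
imputation, plus synthetic-data generators with known ground truth for
every stage.

The package is for comparative biologists who want to ask, on a dated
phylogeny, whether a discrete social trait and a longevity classification
evolved together, and which genes' expression tracks those traits after
controlling for shared ancestry — with every statistical step testable
against simulations where the answer is known.

## The models

**Discrete-trait evolution.** A trait with k states evolves along the tree
as a continuous-time Markov chain with rate matrix Q (rows sum to 0).
Parameterizations: ER (one rate), IC (no direct solitary ↔ group-living
transitions), ARD (all k(k−1) rates free), and reversible-jump MCMC over
rate-class partitions including a zero class. The likelihood is Felsenstein
pruning with exp(Qt) per branch; polymorphic species enter as ambiguity
sets. Rates carry an Exponential(m) prior, m ~ U(0, 2); marginal
likelihoods come from stepping-stone sampling, and models are compared by

    Log BF = 2 × (log ML_complex − log ML_simple)

read as: < 2 simple, 2–5 positive, 5–10 strong, > 10 very strong.

**Correlated evolution.** Two binary traits (a social coding ×
long-lived/short-lived at cutoffs 17/26/35 years, or 0.93/1.38/1.83 in
body-mass-adjusted units) form a joint 4-state chain; the independent model
(4 rates) factorizes exactly into the marginal chains, the dependent model
(8 rates) lets each trait's transition rates depend on the other's state.
Log BF > 2 between their stepping-stone marginal likelihoods calls
correlated evolution. Relative longevity is
`lifespan / (4.88 · mass^0.153)` (mass in g, lifespan in years).

**Phylogenetic signal & ANOVA.** Pagel's λ scales off-diagonal phylogenetic
covariance; λ̂ is the profile-ML over [0, 1] for continuous traits (GLS
mean) or the joint ML with CTMC rates for discrete traits. The
phylogenetic ANOVA refers the observed F to Brownian simulations on the
tree; Hommel-adjusted pairwise comparisons follow.

**Phylogenetic mixed model.** The animal model
y = Xβ + a + e, a ~ N(0, σ²ₐA), e ~ N(0, σ²ₑI) with A the phylogenetic
correlation matrix, sampled by conjugate Gibbs (inverse-gamma V=1,
nu=0.002 priors). Per-gene screens call a gene significant when
pMCMC < 0.05 and |posterior mean| exceeds a cut score — the 0.975 quantile
of the best-fitting normal/logistic distribution of posterior means
(≈ 1.96 for a standard normal).

**Enrichment, normalization, imputation.** SUMSTAT sums member gene scores
and tests them against random same-size sets (with confounder rescaling
and overlap pruning); counts are filtered (<10 in >3 samples; >5% of a
library; <70% species coverage) and normalized as log2(RPKM+1) on
TMM-effective library sizes; missing continuous traits are imputed by the
conditional mean of a multi-trait Brownian model, benchmarked by
NRMSE/Bias under MCAR and MAR missingness.

## Worked example

```python
import numpy as np
from sociophylo import synthetic_data as sd, correlated as co, \
    bayes_engine as be, signal_anova as sa

tree = sd.simulate_yule_tree(200, 1.0, seed=1)

# two binary traits evolved under a strongly dependent joint model
dep = co.build_pair_model("dependent", [0.2, 0.5, 2.0, 0.5,
                                        0.5, 2.0, 0.5, 0.2])
pair, truth = sd.simulate_binary_pair(tree, dep, seed=2)
comp = co.discrete_correlation_test(tree, pair["x"], pair["y"],
                                    be.EngineConfig.quick(seed=3))
print(f"logML dependent   = {comp.logml_complex:.2f}")
print(f"logML independent = {comp.logml_simple:.2f}")
print(f"Log BF = {comp.log_bf:.2f}  ({comp.category})")

# phylogenetic signal of a Brownian trait simulated at lambda = 0.7
bm, _ = sd.simulate_continuous_bm(tree, sigma2=1.0, lam=0.7, seed=4)
fit = sa.lambda_continuous(tree, bm["rep0"])
print(f"lambda = {fit.lam:.2f}  (LR p = {fit.lr_pvalue:.2e})")
```

Output:

```
logML dependent   = -196.72
logML independent = -220.42
Log BF = 47.39  (very strong)
lambda = 0.74  (LR p = 1.06e-20)
```

The dependent generating model is recovered decisively (Log BF ≫ 2), and
λ̂ = 0.74 lands on the generating value 0.7. With traits simulated
independently the same test yields Log BF < 2 (see the test suite's
specificity experiments).

A command-line layer wraps the same functions:

```bash
sociophylo simulate tree --n-tips 200 --seed 1 --out tree.nwk
sociophylo tree scale --tree tree.nwk --target-mean 0.01 --out scaled.nwk
sociophylo discrete-test --tree tree.nwk --traits traits.tsv \
    --x social_binary --y long_lived --profile quick
sociophylo run --config pipeline.yaml
```

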