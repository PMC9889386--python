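# Methods

This note documents the models, algorithms, numerical choices, and
limitations behind `sociophylo`. The package re-implements, as a tested
pipeline, the phylogenetic comparative machinery used to relate mammalian
social organization (solitary / pair-living / group-living) to longevity:
discrete-trait Markov models with Bayesian model comparison, correlated-
evolution tests, phylogenetic signal and ANOVA, phylogenetic mixed models
for trait and gene-expression regression, SUMSTAT gene-set enrichment,
RNA-seq count normalization, and Brownian-motion trait imputation. All
stages are exercisable on synthetic data with known ground truth.

## Trees and phylogenetic covariance

`treeio.PhyloTree` is an array-backed rooted tree with branch lengths in
time-like units. The phylogenetic covariance C has entries
C[i,j] = shared root-to-tip path length of tips i and j; every statistical
module consumes either C or the pruning likelihood directly. The transforms
are defined by their exact effect on C:

- **prune_to** preserves the pairwise shared path lengths of surviving tips
  (unary nodes collapsed, lengths summed).
- **resolve_polytomies** inserts zero-length branches, leaving C unchanged,
  so any random resolution is statistically equivalent.
- **scale_branches_to_mean** multiplies all branches by one constant
  (default target mean 0.01 for rate estimation, so transition rates are
  not driven toward zero on trees measured in tens of millions of years).
  By the CTMC time-rescaling identity this only rescales rate units.
- **lambda_transform** multiplies internal branches by Pagel's lambda and
  restores root-to-tip depths on the pendant edges, scaling off-diagonal
  covariance by exactly lambda. lambda = 1 leaves the tree untouched;
  lambda = 0 yields a star (no signal).

Species names are normalized space-to-underscore on read; all matching
afterwards is exact. Branch scaling, when requested, is applied after
pruning to the analysis taxa.

## Discrete-trait models

A trait with k states (k = 2..4 here) evolves by a continuous-time Markov
chain with generator Q, rows summing to zero. Parameterizations: ER (one
shared rate), IC (for the three social states: no direct
solitary <-> group-living transitions), ARD (k(k-1) free rates), and
arbitrary partitions of the rate positions into shared classes plus a
"zero" class.

The likelihood is Felsenstein pruning with per-branch transition matrices
exp(Q t). Polymorphic species enter as ambiguity sets: the tip partial
vector is the indicator of the allowed states, which is exactly the
marginalization over the unobserved true state. Zero-length branches give
exp(Q*0) = I exactly. The root state carries a uniform prior by default
(stationary and user-supplied options are available and recorded); this is
the conventional choice when the root state is not of interest.

Numerics: exp(Q t) for all branches comes from one eigendecomposition of Q
broadcast over branch lengths, with a scaling-and-squaring (`scipy`
`expm`) fallback whenever the eigenbasis fails a reconstruction check at
1e-9. Rows are clipped to [0, inf) and renormalized to sum to one,
removing O(1e-15) drift. The postorder accumulation rescales partials at
every internal node and carries log-scalers, so likelihoods of thousands of
tips do not underflow. The inner loops are numba-compiled with a pure-numpy
fallback; both paths are compared in tests.

Maximum likelihood (`fit_ml_discrete`) optimizes on the log-rate scale
(L-BFGS-B) from 10 seeded random restarts to escape boundary optima;
standard errors come from the numerical Hessian at the optimum. Boundary
fits (a rate under 1e-8, or fewer than two observed states) are flagged,
not hidden.

## Bayesian engine

Rates carry an Exponential(m) prior whose mean m has a uniform hyperprior
on [0, 2] — the hyper-prior approach used for all model fits. Sampling is
Metropolis-Hastings with multiplicative log-normal proposals per rate
class, and an MH step for m; proposal scales adapt toward 30% acceptance
during burn-in only, so the post-burn-in chain is a valid fixed kernel.

**Reversible jump.** The RJ sampler explores partitions of the off-diagonal
rate positions into shared classes plus a zero class. One dimension move
per sweep reassigns a uniformly chosen position to an existing class, a
fresh class (rate drawn from the exponential prior, whose density cancels
against the proposal), or the zero class; emptied classes are removed. The
model prior is uniform; the Hastings ratio counts forward and reverse
reassignment options. Model ids are canonical strings (classes renamed in
order of first appearance, "Z" for zero), and posterior visit fractions are
reported. The contract is recovery of the generating structure on
simulated data (the shared-rate model on equal-rates data; zero-class
assignment of a forbidden transition), not bit-compatibility with any
external sampler.

**Marginal likelihood.** Stepping-stone sampling along power posteriors
with temperatures beta_k = (k/K)^(1/0.3), which concentrates stones near
the prior where the integrand varies fastest. Each stone warm-starts from
the previous one with a short burn-in (a quarter of the per-stone
iterations). The estimator is validated against the closed-form marginal
likelihood of a conjugate normal model and satisfies the repeat-run
stability criterion (variance below 0.03 across runs at the desk profile).
Log Bayes factors are 2 x (logML_complex - logML_simple), with evidence
read as: < 2 simple model, 2-5 positive, 5-10 strong, > 10 very strong.

**Profiles.** Three engine profiles trade accuracy for time and are
recorded in outputs: `paper` (1000 stones x 10,000 iterations; chains of
100M with 50M burn-in, thin 100) matching the full-scale study protocol;
`desk` (50 x 1,000; 200k/50k/100) for routine single analyses; `quick`
(12 x 200; 4k/1k/2) for batch experiments such as the 100-subset
subsampling protocol and the simulation studies in the test suite. The
quick profile's stepping-stone noise (log-scale SD well under 1) is small
against the Log BF separations produced by strongly dependent vs
independent simulations, which is what the recovery experiments measure.

**Diagnostics.** ESS uses Geyer's initial-positive-sequence estimator
(cross-checked against `arviz` on iid and AR(1) chains); the Gelman-Rubin
R-hat is computed between chains (split halves when only one chain is
available) and flagged at the conventional 1.1.

## Correlated evolution (Discrete test)

Two binary traits form a joint 4-state chain over ((0,0),(0,1),(1,0),(1,1))
with dual transitions forbidden. The independent model has 4 free rates
(each trait's gain/loss, ignoring the other trait); the dependent model has
8 (each trait's gain/loss conditional on the other's state). Independence
implies exact factorization of the joint pruning likelihood into the two
marginal likelihoods — verified to machine precision in tests. The test
computes stepping-stone marginal likelihoods for both models (fixed
parameterizations by default; RJ within each class is available) and calls
correlated evolution when Log BF = 2(logML_dep - logML_indep) > 2.

Binary codings come from `traits.encode_social` (solitary / pair-living /
group-living each against the rest) and `traits.binarize_longevity`
(absolute cutoffs 17/26/35 years; relative cutoffs 0.93/1.38/1.83 on the
body-mass residual), so the six standard combinations are one config-driven
run. Multi-state species are coded as ambiguity sets by default, or dropped
("uni-state subset"). The subsampling robustness protocol draws species
subsets at fractions 0.50-0.95 (step 0.05) with 10 replicates each — 100
comparisons — pruning the tree and re-running the test per subset, and
reports the percentage of comparisons supporting dependence.

## Phylogenetic signal and ANOVA

`lambda_continuous` profiles the multivariate-normal likelihood
y ~ N(mu 1, sigma^2 C(lambda)) over lambda in [0,1] with GLS mean and ML
variance, by grid bracketing plus bounded refinement; the LR test against
lambda = 0 uses chi-square(1) (the convention of the common
implementations, not the boundary mixture). `lambda_discrete` maximizes
the pruning likelihood jointly over lambda and ER rates on the transformed
tree; flat profiles (likelihood gain < 1e-3) resolve to lambda = 0 and are
flagged.

`phylo_anova` refers the observed one-way F to a null distribution from
Brownian simulations on the tree with sigma^2 estimated from the data by
phylogenetic ML (group labels fixed), p = (1 + #{F_null >= F_obs}) /
(nsim + 1). Pairwise post-hoc t statistics use the pooled MSE and their own
simulated nulls (two-sided); the Hommel closed-testing adjustment (via
statsmodels, verified against brute-force closed testing for m <= 5) is
applied across the family of unordered group pairs only. On a star tree the
procedure reduces to classical ANOVA, which the tests verify, and its
type-I error at nominal 0.05 is calibrated to [0.03, 0.07] over 500 null
simulations.

## Phylogenetic mixed model and significance rules

The animal model y = X beta + a + e with a ~ N(0, s2_a A), e ~ N(0, s2_e I)
is sampled by a fully conjugate Gibbs sampler. A is the phylogenetic
covariance scaled to a correlation matrix (tree-height normalization), so
s2_a is in trait-variance units. Priors: flat on beta; inverse-gamma
IG(nu/2, nu V/2) on both variances with the weak (V=1, nu=0.002) default.
The phylogenetic effect is drawn in the eigenbasis of A, where its full
conditional is diagonal; a draw costs one n x n matrix-vector product, and
the eigendecomposition is computed once per tree (cached across genes that
share a missingness pattern). Two chains with between-chain R-hat < 1.1
declare convergence.

pMCMC per coefficient is 2 min(Pr(beta>0), Pr(beta<0)) with a floor of
2/(retained draws). For the per-gene screen, the posterior means of a
coefficient across genes are pooled per model; normal and logistic families
are fitted by ML and compared by the Kolmogorov-Smirnov statistic (AIC
breaks ties); the cut score is the fitted upper 0.975 quantile (a standard
normal gives ~1.96, a unit logistic gives ln 39 ~ 3.66). A gene is called
significant when pMCMC < 0.05 and |posterior mean| > cut, with the sign
giving the direction. Cut scores are fitted per model per coefficient
family and recorded in the output.

Chain profiles: `paper` 1M/100k/thin 500 (the full-scale protocol), `desk`
50k/10k/20, `quick` 4k/1k/3 for genome-scale screens; the profile is part
of the output. Lifestyle is collapsed to aerial vs non-aerial in gene
models so every gene's species subset contains all predictor levels.

## Expression filtering and normalization

Filters run low -> high -> coverage and are idempotent: genes with counts
below 10 in strictly more than 3 samples are removed ("more than 3" read
literally: 4 or more); genes holding more than 5% of any sample's total are
removed; genes detected in fewer than ceil(0.70 n_species) species are
removed. TMM factors follow the published algorithm with its standard
constants — reference sample by upper-quartile proximity to the mean, 30%
two-sided trim on M, 5% on A, delta-method precision weights, factors
normalized to geometric mean one — and are verified against a brute-force
trimmed-mean oracle; expression is log2(RPKM + 1) on TMM-effective library
sizes. Replicate samples collapse to species by the mean of log2 values
(median available).

## SUMSTAT enrichment

A set's score is the sum of member gene scores (absent members contribute
zero and are reported as reduced coverage). Directional analyses zero the
opposing tail before testing. When scores correlate with gene length or
species count (Pearson p < 0.05), scores are standardized within 20
equal-occupancy confounder bins back to the global mean/SD (bins under 5
genes merge leftward). Significance is empirical against random same-size
sets with the +1 correction, so p >= 1/(draws+1) and the null p-values are
super-uniform by construction. Pruning iterates: freeze the most
significant set with p < alpha, delete its genes from all remaining sets,
re-test at reduced sizes (nulls re-drawn at the new size), stop when
nothing reaches alpha. Null draws default to 10,000 (2,000 at desk scale).

## Imputation

The multi-trait Brownian imputer treats the stacked trait matrix as
vec(Y) ~ N(mu (x) 1, R (x) C) with C the phylogenetic correlation matrix;
trait means are GLS, the trait covariance R is pairwise ML over complete
pairs with diagonal-loading shrinkage until positive definite (the
shrinkage is flagged). Missing entries get their exact conditional means
given all observed entries of all traits, with per-entry predictive SDs.
On a star tree this reduces to grand-mean imputation; on a 3-tip tree it
matches the hand-computed conditional normal.

The benchmark masks a complete column under MCAR, MAR-BM (logistic masking
probability in body-mass rank, slope 2 on the standardized rank, trimmed
to the exact count — the pattern label is reproduced; the original
mechanism is not specified quantitatively), or MAR-Phy (masking
concentrated in randomly chosen small clades, padded to the exact count);
fractions 5-50%; at least 10 replicates. Scores: NRMSE = RMSE/range(truth)
and Bias = mean(signed error)/sd(truth) — the normalizers are configurable
and named in every report so comparisons are self-consistent. The
non-phylogenetic comparator is mean imputation.

## Synthetic data: what it does and does not emulate

Generators produce Yule (pure-birth) trees with exactly n tips (ultrametric
by construction, matching a dated-phylogeny setting; tree depth is of order
log n / birth rate, so simulation rates of order 0.2-2 give informative
but unsaturated traits at the 100-1000-tip scales used); discrete traits by
exact Gillespie simulation along branches (agreeing with exp(Qt) to Monte-
Carlo error); correlated binary pairs under explicit dependent/independent
joint models; BM traits at any lambda; expression panels with planted fixed
effects (default: effects on 10-15% of genes at 3 residual SD, phylogenetic
and residual variances 1.0 each); negative-binomial counts; gene sets with
planted score shifts; and the three missingness patterns. Every artifact
carries a `SimulationTruth` (generator, seed, parameters, planted ids), and
identical (generator, parameters, seed) reproduce bit-identical output.

What passing tests on these data do *not* show: robustness to tree
misspecification or calibration error, non-ultrametric trees, model
misspecification of expression noise (real RNA-seq residuals are heavier-
tailed than Gaussian after log transform), phylogenetic non-independence
of gene sets, or taxon-sampling biases that correlate with the traits —
the synthetic MAR mechanisms are simple stand-ins.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run the complete method stack at
reduced problem sizes chosen as the package's own desk-scale defaults:
300-tip trees with 10-20 replicate datasets for the correlated-evolution
recovery experiments (quick engine profile), an 800-tip tree for lambda
recovery, 500 null simulations for ANOVA calibration, 120-gene panels for
the mixed-model screen, 100-150-tip trees for the subsampling and
imputation protocols. The full-scale profiles (`EngineConfig.paper`,
`PmmConfig.paper`) reproduce the published chain lengths and stone counts
and are selected by configuration only.

## Known limitations

- The RJ proposal scheme is a valid sampler over rate-class partitions but
  not a replica of any external implementation; posterior model frequencies
  are comparable in structure, not in third decimal places.
- The chi-square(1) reference for the lambda LR test is conservative at the
  lambda = 0 boundary.
- The harmonic-mean stability check is a warning-only heuristic.
- Gene-model designs with polymorphic social states use the species' first
  listed state in the three-state regression coding (ambiguity sets have no
  regression analogue); the likelihood-based modules handle ambiguity
  exactly.
- The empirical-null enrichment test assumes exchangeable gene scores after
  rescaling; correlated scores (co-expression) inflate its optimism.
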