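# Methods

`fsstab` benchmarks combinations of SNP filter methods, subset sizes and
prediction learners for a continuous quantitative trait, and quantifies the
*stability* of each feature-selection route alongside its predictive
accuracy. This note documents the models, the synthetic-data generator, the
numerical choices, and what the test suite does and does not establish.

## Trait model and phenotype pre-adjustment

The target trait is residual feed intake (RFI): daily feed intake (DFI)
that is not explained by production traits. Metabolic weight is
MW = ((Wstart + Wend)/2)^0.75 with weights in kg (a unit scale factor can
be applied upstream if gram-based MW is wanted). Multivariate outliers on
(ADG, DFI, BFT, MW) are removed within each farm-batch group when the
squared Mahalanobis distance from the group centre exceeds 12, using the
classical (non-robust) group mean and covariance — the screen is a coarse
guard, not a robust-estimation step. RFI is the residual of an OLS
regression of DFI on {1, ADG, BFT, MW}; an intercept is included in both
linear stages so residuals are centered. The adjusted RFI used as the
prediction target is the residual of RFI on farm-batch dummies plus age at
test start and days on test as covariates; farm-batch levels with fewer
than 10 records are dropped (records excluded, not pooled). Adjustment is
idempotent and its residuals are orthogonal to the design, which the suite
asserts directly.

## Genotype quality control

Fixed stage order: SNP call rate ≥ 0.90 and MAF ≥ 0.05 → sample call rate
≥ 0.90 → per-SNP rounded-mean imputation → near-zero-variance removal
(drop constants; drop SNPs whose most-common/second-most-common frequency
ratio exceeds 95/5 *and* whose percent-distinct-values is below 10%) →
greedy pairwise-correlation pruning at |r| > 0.8. Pruning repeatedly takes
the worst remaining pair and drops the member with the larger mean
absolute correlation to all remaining SNPs (lower column index on exact
ties), so the result is deterministic and has no pair above the cutoff.
Correlations are Pearson on imputed, unstandardized genotype counts. The
pipeline is idempotent; re-running it on its own output changes nothing.

## Filter methods

All filters score SNPs on the outer-training fold only and are pure
functions of (fold, seed).

- **spearcor** — |Spearman rank correlation| of each SNP with the target.
  The absolute value is used: a filter ranks relevance regardless of the
  sign of the association.
- **univ.dtree** — per-SNP regression tree (depth 3) evaluated by 5-fold ×
  2-repeat cross-validation; score is minus the mean validation MSE. The
  resampling scheme is a package choice; no canonical setting exists.
- **mrmr** — greedy forward selection maximizing relevance minus mean
  redundancy to the already-selected set. Mutual information uses the
  Gaussian approximation I = −½ ln(1 − ρ²) on Pearson correlations; a
  discretized plug-in estimator is available (`mi_estimator="plugin"`) and
  doubles as the independent oracle in tests. A candidate perfectly
  correlated with a selected SNP has infinite redundancy and is never
  chosen while finite-score alternatives remain.
- **cforest** — conditional permutation importance from a bagged ensemble
  of regression trees (default 100 trees, mtry = ⌊p/3⌋, minimum leaf 5).
  For each tree, a used feature's out-of-bag values are permuted within
  strata defined by the tree's split points on predictors correlated with
  it (|r| > 0.2); the score is the mean out-of-bag MSE increase. The
  ensemble is built in-package because the conditioning step needs the
  per-tree bootstrap indices and split points, which off-the-shelf forest
  implementations do not expose. Results are sensitive to the ensemble
  hyper-parameters; the defaults are documented, not canonical.
- **random** — uniform selection without replacement; the chance benchmark.

Top-k selection breaks score ties by SNP index, deterministically.

## Learners

Features are standardized to mean 0, sd 1 (denominator N−1) using
training-fold statistics only. Hyper-parameters minimize inner-CV MSE over
exhaustive grids; ties break toward stronger regularization (larger λ,
smaller depth / fewer trees, smaller C/γ).

- **Elastic net / LASSO / ridge** — sklearn coordinate descent; the mixing
  weight α ∈ {0.0, 0.1, …, 1.0} (1 = lasso, 0 = ridge) and λ over a
  30-point geometric path from λ_max. λ is on sklearn's internal scale
  (`Ridge`/`ElasticNet` `alpha`); the oracle tests state the closed forms
  at that scale. Nonzero coefficients are the embedded selection;
  |coefficient| on standardized predictors is the variable importance.
- **SVM (RBF)** — ε-insensitive regression, C ∈ {0.001, 0.1, 1, 5, 10},
  γ ∈ {0.005, 0.05, 0.5, 5}, ε fixed at 0.1 (no canonical value exists).
  A configurable feature cap (default 2,000) refuses full-panel fits,
  which are numerically unstable.
- **Gradient boosting** — least-squares boosted trees, depth ∈ {10, 12,
  15, 17}, learning rate ∈ {0.01, 0.02}, trees ∈ {500, 1000, 3000}; same
  feature cap.
- **GBLUP** — y = 1μ + u + ε with u ~ N(0, G σ²_u), ε ~ N(0, I σ²_ε), and
  G the VanRaden genomic relationship matrix
  G = (M − E)(M − E)′ / (2 Σ q_j(1 − q_j)), allele frequencies computed
  from the data. Variances carry scaled inverse-χ² priors in the
  improper-flat limit (df = −2, scale = 0); μ has a flat prior. The Gibbs
  sampler works in the eigenbasis of G, where the rotated breeding-value
  coordinates are conditionally independent, making each sweep O(N) after
  one O(N³) eigendecomposition. Eigenvalues are floored at 1e−8 of the
  maximum for rank-deficient G. Desk defaults are 25,000 iterations,
  2,500 burn-in, thinning 10; longer chains are one config field away.
  Effective sample sizes are estimated with ArviZ and a warning is issued
  below a configurable floor. Either variance can be fixed, which is how
  the sampler is checked against the known-variance mixed-model-equation
  BLUP (agreement within 0.1 posterior SDs). Test-animal predictions use
  the conditional expectation through the train–test blocks of G. A
  variance floor of 1e−12 keeps the chain proper when the data carry no
  signal.

## Nested cross-validation

10 outer folds (sizes differ by ≤ 1, simple random assignment — no
stratification by farm/batch, which the source protocol does not
describe), and 6 inner folds partitioning each outer training set. One
`CVSplit` object is shared by every (filter × size × learner)
configuration. Standardization, filter scores and tuning see only
outer-training data; the suite enforces this with a poisoning test
(perturbing held-out phenotypes must leave fitted-model fingerprints
hash-identical). Per-fold accuracy is the Spearman correlation between
observed and predicted adjusted RFI; a constant prediction scores 0
(it carries no ranking information). Summaries are the median and IQR
(Q3 − Q1, linear-interpolation quantiles) across folds. A failing
configuration is recorded and skipped; others continue.

## Stability estimation

For a system of n > 1 subsets from a p-feature universe, the
chance-corrected stability estimator is

    Φ̂ = 1 − (1/p Σ_i σ²_i) / (d̄/p · (1 − d̄/p)),   σ²_i = n/(n−1) p̂_i(1 − p̂_i)

with p̂_i the selection frequency of feature i and d̄ the mean subset
size. Φ̂ = 1 iff all subsets are identical and has expectation 0 under
uniform random selection; subsets may differ in size (required for
embedded selection). The confidence interval uses the estimator's
asymptotic-normal sampling variance via per-subset influence terms

    φ_j = (1/den) [ mean_i(Z_ji p̂_i) − d_j d̄/p² + (Φ̂/2)(2 d_j d̄/p² − d_j/p − d̄/p + 1) ],
    Var(Φ̂) ≈ (4/n²) Σ_j (φ_j − φ̄)²,  den = d̄/p (1 − d̄/p),

validated here by a coverage simulation (≥ 90/100 random systems cover 0
at α = 0.05) rather than asserted as a reproduction of any published
interval. Subset descriptives are NSNPs = Σ d_j, PDF = |∪S_j| / NSNPs,
and the median/IQR of d_j; for uniform random subsets of size d the
expected PDF is p(1 − ((p−d)/p)^n)/(n·d), used as the analytic oracle.
Score stability is the mean pairwise Pearson correlation of score vectors
and mean Spearman correlation of their ranks (average-tie dense ranks)
across folds; pairs with a constant vector are excluded with a warning.

## Synthetic-data generator

The generator emulates the statistical structure of a grower-pig
genomic-selection dataset at its defaults: 5,708 animals, 9,523 SNPs with
MAF in [0.05, 0.5], 46 farm-batch levels with ≥ 10 records each. Each
SNP's two allele copies are indicators of latent standard Gaussians
falling below the MAF-matched quantile; AR(1) correlation (ld_rho) of the
latents inside non-overlapping blocks induces controllable LD, enough to
exercise correlation pruning and redundancy-aware filters. QTL effects are
drawn N(0, 1) on standardized genotypes and jointly rescaled so the
realized genetic variance fraction equals h² exactly (avoiding h² drift at
small N); optional epistasis adds products of standardized QTL pairs.
DFI is assembled as 1.6·ADG + 15·BFT + 30·MW plus batch effects
(sd 50 g/d), age and test-length slopes (+2 / −1 g/d per day) and the
genetic-plus-environmental RFI signal (sd 150 g/d) — magnitudes chosen
once as realistic values for growing pigs; only the median start/end
weights (31/130 kg) and test ages are anchored to published figures.

What the generator does **not** emulate: a real genome map and
recombination-based LD decay, pedigree/family structure, selection or
genotyping error, non-Gaussian trait residuals, genotype–environment
interaction. Passing tests therefore demonstrate correctness of the
algorithms and the qualitative behaviour of the benchmark (e.g. that
correlation-aware filters are stable and random selection is not), not
field performance on any particular livestock dataset.

## Degenerate inputs and tie-breaks

Constant SNP columns score 0 (spearcor) or are rejected (standardization);
Φ̂ is undefined at d̄ ∈ {0, p} and raises; identical subsets give a
zero-width CI; all-missing SNPs are dropped at imputation with a warning;
a singular within-group covariance names the offending group. All ranking
ties break by column index so repeated runs are byte-identical.

## Problem sizes

The suite and the acceptance script run at reduced sizes chosen as the
package's own desk-scale defaults: stability targets use 50 replicate
systems of 10 subsets from p = 9,523; sampler oracles use N ≤ 200 with
short chains; the end-to-end recovery check uses N = 2,000, p = 1,000,
20 QTL at h² = 0.5. The full-scale settings (paper-scale Gibbs chains,
5,708 × 9,523 panels) are reachable through configuration only.

## Known limitations

- The recovery check's "≥ 15 of 20 causal SNPs in top-50" clause sits at
  the detection boundary under N(0,1) effect draws: with h² = 0.5 spread
  over 20 QTL, effects below |z| ≈ 0.5 (about a third of draws) fall under
  the null maximum of ~980 non-causal correlations, so typical per-fold
  recovery is 13–15 and the corresponding acceptance test fails by design
  honesty rather than implementation error; the stability and accuracy
  clauses of the same check pass with wide margins.
- The Gaussian-MI approximation in mRMR understates dependence for
  strongly non-linear relationships; the plug-in estimator is available
  but slower.
- Conditional permutation importance scales as trees × used features ×
  OOB size and is the slowest filter at full panel width.
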