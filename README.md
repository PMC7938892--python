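# fsstab

Feature-selection **stability** and accuracy benchmarking for genomic
prediction of quantitative traits from SNP panels.

When a trait such as residual feed intake (RFI) is predicted from
thousands of SNP genotypes, different training samples can select quite
different SNP subsets while predicting equally well. That instability
matters for anyone designing low-density genotyping chips or hunting
candidate regions: a subset that changes with every data refresh cannot be
trusted to capture the underlying genetics. `fsstab` runs the whole
benchmark — phenotype pre-adjustment, genotype QC, filter and embedded
feature selection, nested cross-validated prediction with several
learners — and quantifies how *stable* each selection route is, for animal
breeders and method developers working with additive-coded SNP data.

## The core statistic

For a system S = {S₁, …, Sₙ} of n > 1 SNP subsets selected on n different
training sets from a p-SNP universe, stability is estimated with the
chance-corrected estimator

    Φ̂(S) = 1 − (1/p) Σᵢ σ²(fᵢ) / [ d̄/p · (1 − d̄/p) ],
    σ²(fᵢ) = n/(n−1) · p̂(fᵢ)(1 − p̂(fᵢ)),

where p̂(fᵢ) is the selection frequency of SNP fᵢ across the n subsets
and d̄ is the mean subset size. Φ̂ = 1 exactly when all subsets are
identical and has expectation 0 under uniform random selection; an
asymptotic-normal confidence interval is provided. Accuracy is reported
per configuration as the median and interquartile range of the Spearman
correlation between observed and predicted trait across the outer folds.

Alongside Φ̂ the package reports the proportion of distinct features
(PDF = distinct selected SNPs / total selections, 1/n for identical
subsets), subset-size descriptives, and score-based stability (mean
pairwise Pearson/Spearman correlations of per-SNP filter scores).

Filters: Spearman correlation, univariate decision tree, mRMR,
conditional permutation importance of a bagged forest, and random
selection as benchmark. Learners: elastic net, LASSO, ridge, RBF-SVM,
gradient boosting, and Bayesian GBLUP (Gibbs sampler on the VanRaden
genomic relationship matrix). Since the motivating pig dataset is
proprietary, a first-class synthetic-data module generates genotypes with
block LD and component traits with controlled heritability so the entire
pipeline is testable end to end.

## Worked example

```python
import fsstab
from fsstab.crossval import ExperimentConfig, run_experiment
from fsstab.stability import FeatureSubsetSystem, stability_report

cfg = fsstab.SimConfig(n_samples=1000, n_snps=500, n_qtl=15, h2=0.5,
                       ld_block_size=5, ld_rho=0.4, n_farmbatch=6, seed=1)
geno = fsstab.simulate_genotypes(cfg)
pheno, truth = fsstab.simulate_phenotypes(geno, cfg)
geno_qc, qc_report = fsstab.run_qc(geno)
target = fsstab.prepare_target(pheno)   # adjusted RFI per animal

exp = ExperimentConfig(filters=("spearcor", "random"), sizes=(50,),
                       learners=("ridge",), outer_folds=10, inner_folds=6,
                       seed=1)
res = run_experiment(exp, geno_qc, target)
print(res.summary())
for f in ("spearcor", "random"):
    rep = stability_report(FeatureSubsetSystem(
        geno_qc.snps, res.subsets[(f, 50, "filter")]))
    print(f"{f:9s} NOG = {rep.nog:.2f} "
          f"(95% CI {rep.ci[0]:.2f}..{rep.ci[1]:.2f}), PDF = {rep.pdf:.2f}")
```

Output:

```
  filter  size learner  median_sc   iqr_sc  n_folds  n_failed
  random    50   ridge   0.167301 0.283040       10         0
spearcor    50   ridge   0.623982 0.073856       10         0
spearcor  NOG = 0.63 (95% CI 0.61..0.65), PDF = 0.23
random    NOG = -0.00 (95% CI -0.01..0.01), PDF = 0.66
```

Read: with 15 QTL at h² = 0.5, ranking SNPs by Spearman correlation and
predicting with ridge regression gives a median held-out rank correlation
of 0.62 with tight fold-to-fold spread, and the 10 selected 50-SNP subsets
overlap heavily (Φ̂ = 0.63, only 23% of the 500 selections are distinct
SNPs). Random selection of the same subset size predicts far worse and has
stability indistinguishable from chance (Φ̂ ≈ 0) — the qualitative
contrast the benchmark exists to expose.

The same pipeline is scriptable from the shell:

```bash
fs-stab simulate --config sim.yaml --out data/
fs-stab run --config exp.yaml --out results/
fs-stab stability --subsets results/subsets --universe 9523 --out stab.tsv
```

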