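"""Genotype quality control and feature-set reduction.

Fixed stage order: SNP call-rate / minor-allele-frequency filter ->
sample call-rate filter -> mean imputation -> near-zero-variance removal
-> greedy pairwise-correlation pruning.  Re-running the pipeline on its
own output changes nothing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "filter_call_rate_maf",
    "remove_near_zero_variance",
    "prune_correlated",
    "impute_missing",
    "run_qc",
]


def filter_call_rate_maf(
    geno: GenotypeMatrix,
    snp_cr: float = 0.90,
    maf_min: float = 0.05,
    sample_cr: float = 0.90,
) -> GenotypeMatrix:
    """Drop SNPs below the call-rate or MAF thresholds, then samples below
    the sample call-rate threshold. MAF is recomputed afterwards (it is a
    live property of the matrix)."""
    keep_snps = (geno.call_rate >= snp_cr) & (geno.maf >= maf_min)
    v = geno.values.loc[:, keep_snps[keep_snps].index]
    out = GenotypeMatrix(v)
    keep_samples = out.sample_call_rate >= sample_cr
    out = GenotypeMatrix(out.values.loc[keep_samples[keep_samples].index])
    if out.n_snps == 0 or out.n_samples == 0:
        raise ValueError("call-rate/MAF filtering removed everything")
    return out


def remove_near_zero_variance(
    geno: GenotypeMatrix,
    freq_ratio_cut: float = 95.0 / 5.0,
    unique_cut: float = 10.0,
) -> GenotypeMatrix:
    """Drop constant SNPs and SNPs that are both highly imbalanced and of
    low cardinality: frequency ratio of the two most common genotype values
    above ``freq_ratio_cut`` (default 95/5 = 19) AND percent distinct
    values below ``unique_cut`` (default 10%)."""
    if not geno.is_complete:
        raise ValueError("impute missing genotypes before variance filtering")
    n = geno.n_samples
    keep = []
    for snp in geno.snps:
        counts = geno.values[snp].value_counts().sort_values(ascending=False)
        if len(counts) == 1:
            continue  # constant
        ratio = counts.iloc[0] / counts.iloc[1]
        pct_unique = len(counts) / n * 100.0
        if ratio > freq_ratio_cut and pct_unique < unique_cut:
            continue
        keep.append(snp)
    return geno.subset(snps=keep)


def prune_correlated(geno: GenotypeMatrix, cutoff: float = 0.8) -> GenotypeMatrix:
    """Greedy pairwise-correlation pruning on genotype counts.

    While any SNP pair has |Pearson r| above the cutoff, take the pair with
    the largest |r| and remove the member with the larger mean absolute
    correlation to all remaining SNPs (lower column index removed on exact
    ties).  The result has no pair above the cutoff.
    """
    if not geno.is_complete:
        raise ValueError("impute missing genotypes before pruning")
    X = geno.values.to_numpy(dtype=float)
    p = X.shape[1]
    if p < 2:
        return geno
    with np.errstate(invalid="ignore"):
        C = np.abs(np.corrcoef(X, rowvar=False))
    np.fill_diagonal(C, 0.0)
    C = np.nan_to_num(C)
    alive = np.ones(p, dtype=bool)
    while True:
        sub = np.where(alive)[0]
        Cs = C[np.ix_(sub, sub)]
        if Cs.size == 0 or Cs.max() <= cutoff:
            break
        i, j = np.unravel_index(np.argmax(Cs), Cs.shape)
        a, b = sub[i], sub[j]
        mean_a, mean_b = Cs[i].mean(), Cs[j].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = min(a, b)
        alive[drop] = False
    keep = [geno.snps[k] for k in np.where(alive)[0]]
    return geno.subset(snps=keep)


def impute_missing(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the per-SNP rounded mean genotype.

    All-missing SNPs are dropped with a warning.
    """
    v = geno.values.copy()
    all_missing = v.columns[v.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} all-missing SNPs: "
            f"{list(all_missing[:5])}...",
            stacklevel=2,
        )
        v = v.drop(columns=all_missing)
    means = np.round(v.mean(axis=0, skipna=True))
    v = v.fillna(means)
    return GenotypeMatrix(v)


def run_qc(
    geno: GenotypeMatrix,
    snp_cr: float = 0.90,
    maf_min: float = 0.05,
    sample_cr: float = 0.90,
    freq_ratio_cut: float = 95.0 / 5.0,
    unique_cut: float = 10.0,
    corr_cutoff: float = 0.8,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Full QC pipeline in the fixed stage order.

    Returns the filtered matrix and a per-stage report (SNPs/samples
    retained after each stage).
    """
    stages = []

    def log(stage: str, g: GenotypeMatrix) -> None:
        stages.append({"stage": stage, "n_snps": g.n_snps, "n_samples": g.n_samples})

    log("input", geno)
    geno = filter_call_rate_maf(geno, snp_cr, maf_min, sample_cr)
    log("call_rate_maf", geno)
    geno = impute_missing(geno)
    log("impute", geno)
    geno = remove_near_zero_variance(geno, freq_ratio_cut, unique_cut)
    log("near_zero_variance", geno)
    geno = prune_correlated(geno, corr_cutoff)
    log("correlation_pruning", geno)
    return geno, pd.DataFrame(stages)
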