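"""Synthetic SNP genotype and feed-efficiency phenotype generator.

Emulates the statistical structure of a grower-pig genomic-selection
dataset: an additive-coded SNP panel with block-wise linkage
disequilibrium and a minimum minor-allele frequency, and component traits
(daily feed intake, average daily gain, backfat, metabolic weight) from
which a residual-feed-intake-like target with controlled narrow-sense
heritability can be derived, plus farm-batch / age / test-length
systematic effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = ["SimConfig", "SimTruth", "simulate_genotypes", "simulate_phenotypes"]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the real study's scale where known (5,708 animals,
    ~9.5k post-QC SNPs, MAF >= 0.05, farm-batch levels with >= 10 records
    each); trait magnitudes are realistic grower-pig values.
    """

    n_samples: int = 5708
    n_snps: int = 9523
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    n_qtl: int = 100
    h2: float = 0.3
    n_epistatic_pairs: int = 0
    n_farmbatch: int = 46
    missing_rate: float = 0.0
    seed: int = 0

    # trait magnitudes (free parameters; not dictated by the study design)
    rfi_sd: float = 150.0          # g/day, sd of genetic + environmental RFI signal
    batch_sd: float = 50.0         # g/day, sd of farm-batch effects
    age_slope: float = 2.0         # g/day per day of age at test start
    length_slope: float = -1.0     # g/day per day on test
    dfi_coefs: tuple[float, float, float] = (1.6, 15.0, 30.0)  # on ADG, BFT, MW

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_farmbatch < 2:
            raise ValueError("need at least 2 FarmBatch levels")
        if self.n_samples < 10 * self.n_farmbatch:
            raise ValueError(
                "every FarmBatch level needs >= 10 records: "
                f"n_samples={self.n_samples} < 10 * {self.n_farmbatch}"
            )
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class SimTruth:
    """Ground truth of one simulation replicate."""

    qtl_ids: list[str]
    qtl_effects: np.ndarray
    true_genetic_values: np.ndarray
    true_variances: tuple[float, float]  # (sigma_u^2, sigma_e^2)
    epistatic_pairs: list[tuple[str, str]] = field(default_factory=list)


def _latent_ar1(rng: np.random.Generator, n: int, p: int, rho: float,
                block: int) -> np.ndarray:
    """Latent N(0,1) matrix with AR(1) correlation rho inside blocks."""
    z = rng.standard_normal((n, p))
    if rho > 0 and block > 1:
        w = np.sqrt(1.0 - rho**2)
        for start in range(0, p, block):
            for j in range(start + 1, min(start + block, p)):
                z[:, j] = rho * z[:, j - 1] + w * z[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate an additive-coded SNP matrix with block LD.

    Each SNP's two allele copies are indicators of independent latent
    Gaussian layers falling below the MAF-matched quantile; AR(1)
    correlation of the latents within non-overlapping blocks of
    ``ld_block_size`` SNPs induces genotype LD controlled by ``ld_rho``.
    Coding: 0 = minor-allele homozygote, 1 = heterozygote, 2 = major
    homozygote; entries are set missing at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    cut = stats.norm.ppf(mafs)

    minor_count = np.zeros((n, p), dtype=float)
    for _ in range(2):  # two allele layers
        z = _latent_ar1(rng, n, p, config.ld_rho, config.ld_block_size)
        minor_count += z < cut
    geno = 2.0 - minor_count  # 0 = minor homozygote

    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        geno[mask] = np.nan

    samples = [f"A{i:05d}" for i in range(n)]
    snps = [f"SNP{j:05d}" for j in range(p)]
    return GenotypeMatrix(pd.DataFrame(geno, index=samples, columns=snps))


def _scaled_to_var(x: np.ndarray, target_var: float) -> np.ndarray:
    """Center and rescale x to have exactly the target sample variance."""
    x = x - x.mean()
    s = x.std(ddof=1)
    if target_var == 0.0 or s == 0.0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var) / s


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate component traits and a heritable feed-intake target.

    Builds DFI = b1*ADG + b2*BFT + b3*MW + FarmBatch_j + b_age*Age +
    b_len*Length + (g + e), where g is the additive genetic value from
    ``n_qtl`` QTL (optionally plus epistatic pairwise products) rescaled so
    var(g) / var(g + e) equals ``h2`` exactly on the realized sample.  The
    residual-feed-intake derivation applied downstream therefore recovers
    g + e (up to regression projection error), with known heritability.

    Returns the phenotype table (animal_id, DFI, ADG, BFT, Wstart, Wend,
    MW, Age, Length, FarmBatch) and the simulation ground truth.
    """
    config.validate()
    if not geno.is_complete:
        raise ValueError("genotypes must be complete (impute or missing_rate=0)")
    rng = np.random.default_rng(config.seed + 1)
    n = geno.n_samples
    X = geno.values.to_numpy()

    # additive genetic values from standardized QTL genotypes
    qtl_idx = rng.choice(geno.n_snps, size=config.n_qtl, replace=False)
    effects = rng.standard_normal(config.n_qtl)
    Xq = X[:, qtl_idx]
    sd = Xq.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Zq = (Xq - Xq.mean(axis=0)) / sd
    g_raw = Zq @ effects

    epi_pairs: list[tuple[str, str]] = []
    if config.n_epistatic_pairs > 0:
        pair_idx = rng.choice(config.n_qtl, size=(config.n_epistatic_pairs, 2))
        epi_eff = rng.standard_normal(config.n_epistatic_pairs)
        for (a, b), e in zip(pair_idx, epi_eff):
            g_raw = g_raw + e * Zq[:, a] * Zq[:, b]
            epi_pairs.append(
                (geno.snps[qtl_idx[a]], geno.snps[qtl_idx[b]])
            )

    var_u = config.h2 * config.rfi_sd**2
    var_e = (1.0 - config.h2) * config.rfi_sd**2
    g = _scaled_to_var(g_raw, var_u)
    e = _scaled_to_var(rng.standard_normal(n), var_e)

    # systematic environmental effects
    batch = rng.permutation(np.arange(n) % config.n_farmbatch)
    batch_eff = rng.normal(0.0, config.batch_sd, size=config.n_farmbatch)
    age = rng.integers(50, 106, size=n).astype(float)
    length = rng.integers(60, 121, size=n).astype(float)

    # component traits
    wstart = np.clip(rng.normal(31.0, 4.0, size=n), 15.0, None)
    wend = np.clip(wstart + rng.normal(99.0, 10.0, size=n), 40.0, None)
    adg = (wend - wstart) * 1000.0 / length
    bft = np.clip(rng.normal(12.0, 2.0, size=n), 4.0, None)
    mw = ((wstart + wend) / 2.0) ** 0.75

    b1, b2, b3 = config.dfi_coefs
    dfi = (
        b1 * adg
        + b2 * bft
        + b3 * mw
        + batch_eff[batch]
        + config.age_slope * (age - age.mean())
        + config.length_slope * (length - length.mean())
        + g
        + e
    )

    pheno = pd.DataFrame(
        {
            "animal_id": geno.samples,
            "DFI": dfi,
            "ADG": adg,
            "BFT": bft,
            "Wstart": wstart,
            "Wend": wend,
            "MW": mw,
            "Age": age,
            "Length": length,
            "FarmBatch": [f"FB{b:02d}" for b in batch],
        }
    )
    truth = SimTruth(
        qtl_ids=[geno.snps[j] for j in qtl_idx],
        qtl_effects=effects,
        true_genetic_values=g,
        true_variances=(var_u, var_e),
        epistatic_pairs=epi_pairs,
    )
    return pheno, truth
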