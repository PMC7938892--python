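"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GenotypeMatrix", "FilterScore"]


@dataclass
class GenotypeMatrix:
    """Additive-coded SNP matrix (samples x SNPs).

    ``values`` holds floats in {0, 1, 2} with NaN for missing calls;
    coding is 0 = minor-allele homozygote, 1 = heterozygote, 2 = the other
    homozygote.  Call rate and minor-allele frequency are recomputed from
    the current entries, so they stay valid after any row/column removal.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)

    @property
    def samples(self) -> list:
        return list(self.values.index)

    @property
    def snps(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().any().any())

    @property
    def call_rate(self) -> pd.Series:
        """Per-SNP fraction of non-missing calls."""
        return self.values.notna().mean(axis=0)

    @property
    def sample_call_rate(self) -> pd.Series:
        """Per-sample fraction of non-missing calls."""
        return self.values.notna().mean(axis=1)

    @property
    def allele_freq(self) -> pd.Series:
        """Per-SNP frequency of the allele counted by the 0/1/2 coding."""
        return self.values.mean(axis=0, skipna=True) / 2.0

    @property
    def maf(self) -> pd.Series:
        """Per-SNP minor-allele frequency."""
        f = self.allele_freq
        return pd.concat([f, 1.0 - f], axis=1).min(axis=1)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        v = self.values
        if samples is not None:
            v = v.loc[samples]
        if snps is not None:
            v = v[snps]
        return GenotypeMatrix(v.copy())


@dataclass
class FilterScore:
    """Per-SNP relevance scores of one filter on one training fold.

    Higher score = more relevant.  ``ranks`` are dense ranks with 1 the
    best-scoring SNP.
    """

    filter_name: str
    snp_ids: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.snp_ids) != len(self.scores):
            raise ValueError("snp_ids and scores length mismatch")

    @property
    def ranks(self) -> np.ndarray:
        return stats.rankdata(-self.scores, method="dense").astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "score": self.scores, "rank": self.ranks}
        )
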