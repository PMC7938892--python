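"""Readers and writers for the on-disk interchange formats.

Genotypes travel as PLINK ``.raw``-style whitespace-delimited tables
(FID IID PAT MAT SEX PHENOTYPE followed by one additive-coded column per
SNP, NA = missing); phenotypes as CSV; selected subsets as one-SNP-per-line
text files named ``{filter}_{size}_{fold}.txt``; filter scores as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FilterScore, GenotypeMatrix
from .simulate import SimTruth

__all__ = [
    "write_plink_raw",
    "read_plink_raw",
    "read_genotype_csv",
    "write_phenotypes",
    "read_phenotypes",
    "write_truth",
    "read_truth",
    "write_subset",
    "read_subset",
    "write_scores",
    "read_scores",
]

_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    df = geno.values.copy()
    out = pd.DataFrame(
        {
            "FID": geno.samples,
            "IID": geno.samples,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    for snp in df.columns:
        col = df[snp].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        out[f"{snp}_A"] = col.to_numpy()  # positional: out has a RangeIndex
    out.to_csv(path, sep=" ", index=False)


def read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    missing = [c for c in _META if c not in df.columns]
    if missing:
        raise ValueError(f"not a .raw table, missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in _META]
    values = df[snp_cols].astype(float)
    # strip the trailing _<allele> suffix PLINK appends to SNP names
    values.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    values.index = df["IID"].astype(str)
    return GenotypeMatrix(values)


def read_genotype_csv(path) -> GenotypeMatrix:
    """CSV alternative: first column sample ID, remaining columns SNPs."""
    df = pd.read_csv(path, index_col=0)
    return GenotypeMatrix(df.astype(float))


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: SimTruth, path) -> None:
    payload = {
        "qtl_ids": list(truth.qtl_ids),
        "qtl_effects": np.asarray(truth.qtl_effects).tolist(),
        "true_genetic_values": np.asarray(truth.true_genetic_values).tolist(),
        "true_variances": list(truth.true_variances),
        "epistatic_pairs": [list(p) for p in truth.epistatic_pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimTruth:
    d = json.loads(Path(path).read_text())
    return SimTruth(
        qtl_ids=d["qtl_ids"],
        qtl_effects=np.asarray(d["qtl_effects"]),
        true_genetic_values=np.asarray(d["true_genetic_values"]),
        true_variances=tuple(d["true_variances"]),
        epistatic_pairs=[tuple(p) for p in d["epistatic_pairs"]],
    )


def write_subset(snp_ids, path) -> None:
    Path(path).write_text("\n".join(map(str, snp_ids)) + "\n")


def read_subset(path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_scores(score: FilterScore, path) -> None:
    score.to_frame().to_csv(path, sep="\t", index=False)


def read_scores(path, filter_name: str = "") -> FilterScore:
    df = pd.read_csv(path, sep="\t")
    return FilterScore(filter_name or "unknown", df["snp_id"].tolist(),
                       df["score"].to_numpy(float))
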