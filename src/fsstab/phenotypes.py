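"""Derivation of the adjusted residual-feed-intake (RFI) target.

Pipeline: metabolic weight -> within-farm-batch multivariate outlier
removal (squared Mahalanobis distance on ADG, DFI, BFT, MW) -> RFI as the
residual of DFI regressed on ADG, BFT and MW -> pre-adjustment for the
systematic environmental effects FarmBatch (categorical), age at test
start and days on test.  The adjusted residuals are the prediction target
of the downstream genomic models; lower RFI = more feed-efficient.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "compute_metabolic_weight",
    "flag_multivariate_outliers",
    "derive_rfi",
    "adjust_rfi",
    "prepare_target",
]

OUTLIER_TRAITS = ["ADG", "DFI", "BFT", "MW"]


def compute_metabolic_weight(wstart, wend):
    """Metabolic weight: mean of start/end test weights raised to 0.75.

    Weights are used as given (kg by default); the caller may rescale if
    another unit is required.
    """
    wstart = np.asarray(wstart, dtype=float)
    wend = np.asarray(wend, dtype=float)
    if np.any(wstart <= 0) or np.any(wend <= 0):
        raise ValueError("weights must be positive")
    return ((wstart + wend) / 2.0) ** 0.75


def flag_multivariate_outliers(
    table: pd.DataFrame,
    threshold: float = 12.0,
    group_col: str = "FarmBatch",
    traits: list[str] | None = None,
) -> pd.Series:
    """Retention mask: False where the squared Mahalanobis distance of
    (ADG, DFI, BFT, MW) from its farm-batch group centre exceeds the
    threshold (default 12).

    Distances use the classical per-group mean and sample covariance.
    Groups must have more records than traits; a singular group covariance
    raises an error naming the group.
    """
    traits = traits or OUTLIER_TRAITS
    mask = pd.Series(True, index=table.index)
    for group, sub in table.groupby(group_col, observed=True):
        X = sub[traits].to_numpy(dtype=float)
        if X.shape[0] <= X.shape[1]:
            raise ValueError(
                f"group {group!r} has {X.shape[0]} records, need more than "
                f"{X.shape[1]} to estimate its covariance"
            )
        mu = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance in group {group!r}") from err
        dev = X - mu
        d2 = np.einsum("ij,jk,ik->i", dev, inv, dev)
        mask.loc[sub.index] = d2 <= threshold
    return mask


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    model = sm.OLS(y, X)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return model.fit().resid


def derive_rfi(table: pd.DataFrame) -> pd.Series:
    """RFI = residual of the OLS regression of DFI on ADG, BFT and MW.

    An intercept is included, so residuals sum to zero.  Outlier records
    are assumed already removed.
    """
    X = sm.add_constant(table[["ADG", "BFT", "MW"]].to_numpy(dtype=float))
    resid = _ols_residuals(table["DFI"].to_numpy(dtype=float), X)
    return pd.Series(resid, index=table.index, name="RFI")


def adjust_rfi(
    rfi: pd.Series,
    age: pd.Series,
    length: pd.Series,
    farmbatch: pd.Series,
    min_batch_records: int = 10,
) -> pd.Series:
    """Pre-adjust RFI for systematic environmental effects.

    Fits RFI ~ FarmBatch + Age + Length (fixed effects, intercept via the
    batch dummies) and returns the residuals e_ij, the prediction target.
    FarmBatch levels with fewer than ``min_batch_records`` records are
    dropped with a warning and their records excluded (NaN in the output).
    """
    farmbatch = farmbatch.astype(str)
    counts = farmbatch.value_counts()
    small = counts[counts < min_batch_records].index.tolist()
    keep = ~farmbatch.isin(small)
    if small:
        warnings.warn(
            f"dropping FarmBatch levels with < {min_batch_records} records: "
            f"{sorted(small)} ({int((~keep).sum())} records excluded)",
            stacklevel=2,
        )
    out = pd.Series(np.nan, index=rfi.index, name="adjRFI")
    fb = farmbatch[keep]
    dummies = pd.get_dummies(fb, dtype=float)  # full dummy set, no intercept
    X = np.column_stack(
        [dummies.to_numpy(), age[keep].to_numpy(float), length[keep].to_numpy(float)]
    )
    # constant covariates are collinear with the batch dummies: drop them
    cols = [True] * dummies.shape[1] + [
        np.ptp(age[keep].to_numpy(float)) > 0,
        np.ptp(length[keep].to_numpy(float)) > 0,
    ]
    X = X[:, np.asarray(cols)]
    out.loc[keep] = _ols_residuals(rfi[keep].to_numpy(dtype=float), X)
    return out


def prepare_target(
    table: pd.DataFrame,
    outlier_threshold: float = 12.0,
    min_batch_records: int = 10,
) -> pd.Series:
    """Full phenotype pipeline: outlier removal -> RFI -> adjustment.

    Returns the adjusted RFI indexed by animal_id; removed or excluded
    animals are absent from the result.
    """
    table = table.set_index("animal_id") if "animal_id" in table.columns else table
    mask = flag_multivariate_outliers(table, threshold=outlier_threshold)
    kept = table.loc[mask]
    rfi = derive_rfi(kept)
    adj = adjust_rfi(
        rfi,
        kept["Age"],
        kept["Length"],
        kept["FarmBatch"],
        min_batch_records=min_batch_records,
    )
    return adj.dropna()
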