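"""Filter feature-selection methods for SNP panels.

Five filters score/rank SNPs by relevance for a continuous target on one
training fold: Spearman correlation (spearcor), univariate decision tree
(univ.dtree), maximum-relevance-minimum-redundancy (mrmr), conditional
permutation importance of a bagged forest (cforest), and uniform random
selection as benchmark.  All are pure functions of (training fold, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import RepeatedKFold
from sklearn.tree import DecisionTreeRegressor

from .containers import FilterScore

__all__ = [
    "score_spearcor",
    "score_univ_dtree",
    "score_mrmr",
    "score_cforest_cpi",
    "select_random",
    "select_top_k",
    "gaussian_mi",
    "plugin_mi",
    "MrmrState",
]


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, list(range(X.shape[1]))


def score_spearcor(X, y) -> FilterScore:
    """Relevance = |Spearman rank correlation| of each SNP with the target.

    Constant columns score 0 with a warning.  Rank-based, hence invariant
    to monotone transformations of either variable.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    ry = stats.rankdata(y)
    rX = np.apply_along_axis(stats.rankdata, 0, Xm)
    ry_c = ry - ry.mean()
    rX_c = rX - rX.mean(axis=0)
    denom = np.sqrt((rX_c**2).sum(axis=0) * (ry_c**2).sum())
    const = denom == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant column(s) scored 0", stacklevel=2
        )
        denom[const] = 1.0
    rho = (rX_c.T @ ry_c) / denom
    rho[const] = 0.0
    return FilterScore("spearcor", ids, np.abs(rho))


def score_univ_dtree(
    X, y, folds: int = 5, repeats: int = 2, max_depth: int = 3, seed: int = 0
) -> FilterScore:
    """Relevance = resampled performance of a single-feature regression tree.

    For each SNP a depth-limited tree on that feature alone is evaluated by
    repeated k-fold cross-validation; the score is minus the mean validation
    MSE (higher = more relevant).  Fold assignment is a seeded shuffle of
    the sample indices, shared across features.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * folds:
        raise ValueError(f"need N >= {2 * folds} samples")
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(rkf.split(np.arange(n)))
    scores = np.empty(Xm.shape[1])
    for k in range(Xm.shape[1]):
        xk = Xm[:, [k]]
        mse = 0.0
        for tr, va in splits:
            tree = DecisionTreeRegressor(max_depth=max_depth, random_state=0)
            tree.fit(xk[tr], y[tr])
            pred = tree.predict(xk[va])
            mse += np.mean((y[va] - pred) ** 2)
        scores[k] = -mse / len(splits)
    return FilterScore("univ.dtree", ids, scores)


def gaussian_mi(rho: np.ndarray) -> np.ndarray:
    """Mutual information of a bivariate Gaussian with correlation rho:
    I = -1/2 ln(1 - rho^2).  |rho| = 1 gives +inf."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore"):
        return -0.5 * np.log1p(-np.clip(rho**2, 0.0, 1.0))


def plugin_mi(x: np.ndarray, y: np.ndarray, bins: int = 4) -> float:
    """Discretized plug-in mutual-information estimator (nats).

    Bins each variable at its quantiles (discrete variables such as 0/1/2
    genotypes keep their natural levels) and computes MI of the empirical
    joint distribution.  Used as an independent check of the Gaussian
    approximation and available as an mRMR config option.
    """

    def discretize(v):
        v = np.asarray(v, dtype=float)
        if len(np.unique(v)) <= bins:
            _, codes = np.unique(v, return_inverse=True)
            return codes
        edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
        return np.digitize(v, np.unique(edges))

    cx, cy = discretize(x), discretize(y)
    joint = pd.crosstab(cx, cy).to_numpy(dtype=float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


@dataclass
class MrmrState:
    """Greedy mRMR bookkeeping: selected set, per-candidate relevance
    I(Y; X_k), and the running sum of redundancies to the selected set."""

    selected: list[int] = field(default_factory=list)
    relevance: np.ndarray | None = None
    redundancy_sum: np.ndarray | None = None


def score_mrmr(
    X, y, k: int | None = None, mi_estimator: str = "gaussian"
) -> tuple[FilterScore, list]:
    """Greedy maximum-relevance-minimum-redundancy selection.

    Step 1 picks the candidate with maximal mutual information I(Y; X);
    each later step picks argmax_k [ I(Y; X_k) - (1/|S|) sum_{j in S}
    I(X_k; X_j) ] over candidates k not in the selected set S.  Mutual
    information is by default the Gaussian approximation
    -1/2 ln(1 - rho^2) on Pearson correlations ("gaussian"); "plugin" uses
    the discretized estimator.

    Returns a FilterScore whose scores encode the selection order (the
    t-th selected SNP scores p - t + 1; unselected SNPs score below every
    selected one, ordered by their final-step criterion) and the selected
    SNP-ID list in selection order.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    p = Xm.shape[1]
    k = p if k is None else int(k)
    if k > p:
        raise ValueError(f"k={k} exceeds p={p}")

    if mi_estimator == "gaussian":
        sx = Xm.std(axis=0)
        sx[sx == 0] = np.nan
        Xc = (Xm - Xm.mean(axis=0)) / sx
        yc = (y - y.mean()) / (y.std() or 1.0)
        rel = gaussian_mi(np.nan_to_num(Xc.T @ yc / len(y)))

        def pair_mi(j):  # MI of every candidate with selected SNP j
            return gaussian_mi(np.nan_to_num(Xc.T @ Xc[:, j] / len(y)))

    elif mi_estimator == "plugin":
        rel = np.array([plugin_mi(Xm[:, j], y) for j in range(p)])

        def pair_mi(j):
            return np.array([plugin_mi(Xm[:, i], Xm[:, j]) for i in range(p)])

    else:
        raise ValueError(f"unknown mi_estimator {mi_estimator!r}")

    state = MrmrState(relevance=rel, redundancy_sum=np.zeros(p))
    candidate = np.ones(p, dtype=bool)
    crit = rel.copy()
    for _ in range(k):
        masked = np.where(candidate, crit, -np.inf)
        best = int(np.argmax(masked))  # argmax breaks ties at lowest index
        state.selected.append(best)
        candidate[best] = False
        if candidate.any():
            # redundancy of +inf (|rho|=1) permanently disqualifies a
            # candidate while finite-score alternatives remain
            state.redundancy_sum = state.redundancy_sum + pair_mi(best)
            crit = rel - state.redundancy_sum / len(state.selected)

    scores = np.empty(p)
    for t, j in enumerate(state.selected):
        scores[j] = p - t
    unsel = np.where(candidate)[0]
    if len(unsel):
        u = crit[unsel]
        u = np.where(np.isfinite(u), u, -1e18)
        order = unsel[np.argsort(-u, kind="stable")]
        for t, j in enumerate(order):
            scores[j] = p - k - t
    return FilterScore("mrmr", ids, scores), [ids[j] for j in state.selected]


def _tree_strata(tree: DecisionTreeRegressor, X: np.ndarray,
                 cond_vars: np.ndarray) -> np.ndarray:
    """Stratum label per row: joint bin over the tree's split points on the
    conditioning variables.  Rows in one stratum agree on every cut the
    tree actually uses for those variables."""
    feat = tree.tree_.feature
    thr = tree.tree_.threshold
    labels = np.zeros(X.shape[0], dtype=np.int64)
    for v in cond_vars:
        cuts = np.unique(thr[feat == v])
        if len(cuts) == 0:
            continue
        labels = labels * (len(cuts) + 1) + np.searchsorted(cuts, X[:, v])
    return labels


def score_cforest_cpi(
    X,
    y,
    n_trees: int = 100,
    mtry: int | None = None,
    cond_threshold: float = 0.2,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> FilterScore:
    """Conditional permutation importance from a bagged forest.

    Fits an ensemble of regression trees on bootstrap samples (``mtry``
    candidate features per split).  For each tree and each feature the tree
    splits on, the feature's out-of-bag values are permuted *within strata*
    defined by the tree's split points on the other predictors correlated
    with it (|Pearson r| > ``cond_threshold``); the score is the mean
    increase in out-of-bag MSE across trees.  Conditioning isolates a
    predictor's own contribution from that of correlated neighbours.
    Features never split on score exactly 0.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n_trees < 10:
        warnings.warn("fewer than 10 trees gives unstable importances",
                      stacklevel=2)
    mtry = mtry if mtry is not None else max(1, p // 3)
    rng = np.random.default_rng(seed)

    with np.errstate(invalid="ignore"):
        C = np.abs(np.corrcoef(Xm, rowvar=False))
    C = np.nan_to_num(np.atleast_2d(C))
    np.fill_diagonal(C, 0.0)

    importances = np.zeros(p)
    counts = np.zeros(p)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(Xm[boot], y[boot])
        Xo = Xm[oob]
        base_mse = np.mean((y[oob] - tree.predict(Xo)) ** 2)
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for v in used:
            cond = np.where((C[v] > cond_threshold))[0]
            cond = cond[np.isin(cond, used)]
            strata = _tree_strata(tree, Xo, cond)
            Xp = Xo.copy()
            for s in np.unique(strata):
                idx = np.where(strata == s)[0]
                Xp[idx, v] = Xo[rng.permutation(idx), v]
            perm_mse = np.mean((y[oob] - tree.predict(Xp)) ** 2)
            importances[v] += perm_mse - base_mse
        counts += 1  # mean over all trees: unused features contribute 0
    scores = importances / np.maximum(counts, 1)
    return FilterScore("cforest", ids, scores)


def select_random(snp_ids, k: int, seed: int = 0) -> list:
    """Uniform sample of k SNP IDs without replacement (benchmark filter)."""
    snp_ids = list(snp_ids)
    if k > len(snp_ids):
        raise ValueError(f"k={k} exceeds p={len(snp_ids)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(snp_ids), size=k, replace=False)
    return [snp_ids[i] for i in sorted(idx)]


def select_top_k(score: FilterScore, k: int) -> list:
    """The k best-scoring SNP IDs; ties broken by SNP index."""
    if k > len(score.snp_ids):
        raise ValueError(f"k={k} exceeds p={len(score.snp_ids)}")
    order = np.argsort(-score.scores, kind="stable")
    return [score.snp_ids[i] for i in order[:k]]
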