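"""Prediction methods for the genomic models.

Six learners share a common interface: elastic net / LASSO / ridge
(penalized regression with embedded selection), RBF support-vector
regression, gradient-boosted trees, and Bayesian GBLUP via Gibbs sampling.
Hyper-parameters are tuned by grid search on inner-cross-validation MSE;
ties break toward stronger regularization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.svm import SVR

__all__ = [
    "PenalizedRegSpec",
    "SvmSpec",
    "GbSpec",
    "GblupSpec",
    "FittedModel",
    "standardize_features",
    "fit_penalized_regression",
    "fit_svm_rbf",
    "fit_gradient_boosting",
    "compute_grm",
    "fit_gblup_gibbs",
    "GblupFit",
]

ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass
class PenalizedRegSpec:
    """Elastic-net family: ``alpha`` is the L1 mixing weight (0 = ridge,
    1 = lasso); ``lam`` the penalty strength on the sklearn scale
    (ElasticNet/Ridge ``alpha``), or "auto" for an inner-CV path."""

    alpha_grid: Sequence[float] = ALPHA_GRID
    lam: float | str = "auto"
    n_lambdas: int = 30
    max_iter: int = 50_000


@dataclass
class SvmSpec:
    C_grid: Sequence[float] = (0.001, 0.1, 1.0, 5.0, 10.0)
    gamma_grid: Sequence[float] = (0.005, 0.05, 0.5, 5.0)
    epsilon: float = 0.1
    feature_cap: int = 2000


@dataclass
class GbSpec:
    depth_grid: Sequence[int] = (10, 12, 15, 17)
    learning_rate_grid: Sequence[float] = (0.01, 0.02)
    n_trees_grid: Sequence[int] = (500, 1000, 3000)
    feature_cap: int = 2000


@dataclass
class GblupSpec:
    """Gibbs settings; desk-scale defaults, paper-scale available
    (250,000 / 25,000 / 10).  ``prior_df``/``prior_scale`` are the scaled
    inverse-chi-squared hyper-parameters for (sigma_u^2, sigma_e^2);
    (-2, 0) is the improper flat limit.  ``fixed_variances`` pins either
    variance for oracle comparisons."""

    n_iter: int = 25_000
    burn_in: int = 2_500
    thin: int = 10
    prior_df: tuple[float, float] = (-2.0, -2.0)
    prior_scale: tuple[float, float] = (0.0, 0.0)
    fixed_variances: tuple[float | None, float | None] = (None, None)
    ess_floor: float = 100.0
    seed: int = 0


@dataclass
class FittedModel:
    """A fitted learner: prediction callable plus selection metadata."""

    name: str
    predict_fn: object
    best_params: dict = field(default_factory=dict)
    selected_snps: list | None = None       # embedded selection, if any
    importance: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X)
        return self.predict_fn(X)


def standardize_features(X_train, X_test=None):
    """Standardize columns to mean 0, sd 1 (denominator N-1) using
    *training* statistics only; the test block is transformed with the same
    means and sds.  Raises on constant training columns (QC should have
    removed them)."""
    cols = list(X_train.columns) if isinstance(X_train, pd.DataFrame) else None
    Xtr = np.asarray(X_train, dtype=float)
    means = Xtr.mean(axis=0)
    sds = Xtr.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = np.where(sds == 0)[0]
        names = [cols[i] for i in bad] if cols else list(bad)
        raise ValueError(f"constant training column(s): {names[:5]}")
    Xtr_s = (Xtr - means) / sds
    Xte_s = None
    if X_test is not None:
        Xte = np.asarray(X_test, dtype=float)
        Xte_s = (Xte - means) / sds
        if isinstance(X_test, pd.DataFrame):
            Xte_s = pd.DataFrame(Xte_s, index=X_test.index, columns=cols)
    if cols is not None:
        Xtr_s = pd.DataFrame(Xtr_s, index=X_train.index, columns=cols)
    return Xtr_s, Xte_s, means, sds


def _inner_folds(inner_assignments: np.ndarray):
    """(train_idx, val_idx) pairs from a per-row inner-fold label vector."""
    folds = np.unique(inner_assignments)
    for f in folds:
        va = np.where(inner_assignments == f)[0]
        tr = np.where(inner_assignments != f)[0]
        yield tr, va


def _grid_search(fit_one, grid, X, y, inner_assignments):
    """Exhaustive grid search on inner-CV MSE.  ``grid`` is ordered from
    weakest to strongest regularization; ties take the *last* minimum, i.e.
    the stronger regularization."""
    best_mse, best_params = np.inf, None
    for params in grid:
        mse = 0.0
        n_folds = 0
        for tr, va in _inner_folds(inner_assignments):
            model = fit_one(X[tr], y[tr], params)
            mse += np.mean((y[va] - model.predict(X[va])) ** 2)
            n_folds += 1
        mse /= n_folds
        if mse <= best_mse:
            best_mse, best_params = mse, params
    return best_params, best_mse


def _lambda_path(X, y, l1_ratio, n_lambdas):
    n = X.shape[0]
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * max(l1_ratio, 1e-3))
    return np.geomspace(lam_max * 1e-4, lam_max, n_lambdas)


def _fit_enet_point(X, y, alpha, lam, max_iter):
    if lam == 0:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        model = lambda Z: coef[0] + Z @ coef[1:]  # noqa: E731
        return _Plain(model, coef[1:])
    if alpha == 0.0:
        m = Ridge(alpha=lam).fit(X, y)
    else:
        m = ElasticNet(alpha=lam, l1_ratio=alpha, max_iter=max_iter).fit(X, y)
        if m.n_iter_ is not None and m.n_iter_ >= max_iter:
            raise RuntimeError(
                f"elastic net did not converge at alpha={alpha}, lambda={lam}"
            )
    return m


class _Plain:
    def __init__(self, fn, coef):
        self.fn, self.coef_ = fn, coef

    def predict(self, X):
        return self.fn(X)


def fit_penalized_regression(
    X, y, spec: PenalizedRegSpec | None = None, inner_cv: np.ndarray | None = None
) -> FittedModel:
    """Elastic-net regression with embedded feature selection.

    Minimizes the elastic-net objective at the (alpha, lambda) pair with
    the lowest inner-CV MSE (alpha = L1 mixing, grid 0..1 by 0.1 by
    default; lambda over a geometric path unless given).  lambda is on the
    sklearn internal scale: Ridge penalizes ``lam * ||b||^2`` on the
    summed-squares loss, ElasticNet uses the 1/(2n)-scaled loss.  Nonzero
    coefficients are the embedded SNP selection; |coef| on standardized
    predictors is the variable importance.
    """
    spec = spec or PenalizedRegSpec()
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def fit_one(Xt, yt, params):
        a, lam = params
        return _fit_enet_point(Xt, yt, a, lam, spec.max_iter)

    if spec.lam == "auto":
        if inner_cv is None:
            raise ValueError("lam='auto' requires inner_cv assignments")
        grid = []
        for a in spec.alpha_grid:
            for lam in _lambda_path(Xm, y, a, spec.n_lambdas):
                grid.append((a, lam))
        # weakest -> strongest so ties favor stronger regularization
        grid.sort(key=lambda t: (t[0], t[1]))
        best, _ = _grid_search(fit_one, grid, Xm, y, inner_cv)
    elif inner_cv is not None and len(spec.alpha_grid) > 1:
        grid = [(a, spec.lam) for a in spec.alpha_grid]
        best, _ = _grid_search(fit_one, grid, Xm, y, inner_cv)
    else:
        best = (spec.alpha_grid[0], spec.lam)

    model = _fit_enet_point(Xm, y, best[0], best[1], spec.max_iter)
    coef = np.asarray(model.coef_)
    nz = np.flatnonzero(coef)
    selected = [cols[i] for i in nz] if cols else list(nz)
    return FittedModel(
        name="enet",
        predict_fn=model.predict,
        best_params={"alpha": best[0], "lambda": best[1]},
        selected_snps=selected,
        importance=np.abs(coef),
    )


def fit_svm_rbf(
    X, y, spec: SvmSpec | None = None, inner_cv: np.ndarray | None = None
) -> FittedModel:
    """Epsilon-insensitive RBF support-vector regression, (C, gamma) tuned
    on inner-CV MSE.  Refuses feature counts above the configured cap
    (numerically unstable at full panel width)."""
    spec = spec or SvmSpec()
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xm.shape[1] > spec.feature_cap:
        raise ValueError(
            f"feature cap: p={Xm.shape[1]} exceeds {spec.feature_cap}; "
            "pre-select SNPs first"
        )

    def fit_one(Xt, yt, params):
        C, g = params
        return SVR(kernel="rbf", C=C, gamma=g, epsilon=spec.epsilon).fit(Xt, yt)

    grid = [(C, g) for C in spec.C_grid for g in spec.gamma_grid]
    if inner_cv is not None:
        # larger C / gamma = less regularization: order so ties pick smaller
        grid.sort(key=lambda t: (-t[0], -t[1]))
        best, _ = _grid_search(fit_one, grid, Xm, y, inner_cv)
    else:
        best = grid[0]
    model = fit_one(Xm, y, best)
    return FittedModel(
        name="svm",
        predict_fn=model.predict,
        best_params={"C": best[0], "gamma": best[1]},
    )


def fit_gradient_boosting(
    X,
    y,
    spec: GbSpec | None = None,
    inner_cv: np.ndarray | None = None,
    seed: int = 0,
) -> FittedModel:
    """Least-squares gradient-boosted regression trees; depth, learning
    rate and tree count tuned on inner-CV MSE (ties -> smaller depth and
    fewer trees).  Deterministic given the seed."""
    spec = spec or GbSpec()
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xm.shape[1] > spec.feature_cap:
        raise ValueError(
            f"feature cap: p={Xm.shape[1]} exceeds {spec.feature_cap}; "
            "pre-select SNPs first"
        )

    def fit_one(Xt, yt, params):
        depth, lr, n_trees = params
        return GradientBoostingRegressor(
            max_depth=depth,
            learning_rate=lr,
            n_estimators=n_trees,
            random_state=seed,
        ).fit(Xt, yt)

    grid = [
        (d, lr, nt)
        for d in spec.depth_grid
        for lr in spec.learning_rate_grid
        for nt in spec.n_trees_grid
    ]
    if inner_cv is not None:
        grid.sort(key=lambda t: (-t[0], -t[2], -t[1]))
        best, _ = _grid_search(fit_one, grid, Xm, y, inner_cv)
    else:
        best = grid[0]
    model = fit_one(Xm, y, best)
    return FittedModel(
        name="gb",
        predict_fn=model.predict,
        best_params={"depth": best[0], "learning_rate": best[1],
                     "n_trees": best[2]},
    )


def compute_grm(M, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    G = (M - E)(M - E)' / (2 * sum_j q_j (1 - q_j)), where E has 2*q_j in
    column j and q_j is the frequency of the allele counted by the 0/1/2
    coding (computed from the data unless supplied).  Mean diagonal is ~1
    for data in Hardy-Weinberg proportions.
    """
    Mm = np.asarray(M, dtype=float)
    if np.isnan(Mm).any():
        raise ValueError("GRM requires complete genotypes")
    q = Mm.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    denom = 2.0 * np.sum(q * (1.0 - q))
    if denom == 0:
        raise ValueError("all allele frequencies are 0 or 1: zero denominator")
    W = Mm - 2.0 * q
    return W @ W.T / denom


def _ess(chain: np.ndarray) -> float:
    """Effective sample size (initial positive sequence estimator)."""
    import arviz

    return float(arviz.ess(np.asarray(chain)))


@dataclass
class GblupFit:
    mu: float
    u: np.ndarray                      # posterior mean breeding values (train)
    var_u: float
    var_e: float
    ess: dict
    samples: dict
    train_index: np.ndarray | None = None
    G: np.ndarray | None = None

    def predict(self, test_index: np.ndarray) -> np.ndarray:
        """Conditional expectation of test breeding values given training
        posterior means, via the train-test blocks of G."""
        Gtt = self.G[np.ix_(self.train_index, self.train_index)]
        Gst = self.G[np.ix_(test_index, self.train_index)]
        jitter = 1e-8 * np.trace(Gtt) / Gtt.shape[0]
        alpha = np.linalg.solve(Gtt + jitter * np.eye(Gtt.shape[0]), self.u)
        return self.mu + Gst @ alpha


def fit_gblup_gibbs(y, G, spec: GblupSpec | None = None) -> GblupFit:
    """Bayesian GBLUP: y = 1*mu + u + e with u ~ N(0, G sigma_u^2),
    e ~ N(0, I sigma_e^2), scaled inverse-chi-squared variance priors
    (flat limit by default) and a flat prior on mu.

    The sampler works in the eigenbasis of G (u = U v with G = U W U'),
    where the v_i are conditionally independent, so each sweep is O(N):
    block updates of (mu, v) alternate with the two variance draws.
    Returns thinned post-burn-in posterior means and effective sample
    sizes; warns when an ESS falls below the configured floor.
    """
    spec = spec or GblupSpec()
    if spec.burn_in >= spec.n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    y = np.asarray(y, dtype=float)
    G = np.asarray(G, dtype=float)
    N = len(y)
    rng = np.random.default_rng(spec.seed)

    w, U = np.linalg.eigh((G + G.T) / 2.0)
    w = np.maximum(w, 1e-8 * max(w.max(), 1.0))  # PSD jitter
    yt = U.T @ y
    t = U.T @ np.ones(N)

    fix_u, fix_e = spec.fixed_variances
    var_u = fix_u if fix_u is not None else max(np.var(y) / 2.0, 1e-6)
    var_e = fix_e if fix_e is not None else max(np.var(y) / 2.0, 1e-6)
    mu = y.mean()
    v = np.zeros(N)
    df_u, df_e = spec.prior_df
    S_u, S_e = spec.prior_scale

    keep = {"mu": [], "var_u": [], "var_e": [], "v": []}
    for it in range(spec.n_iter):
        # mu | v, var_e  (flat prior)
        mu = rng.normal(t @ (yt - v) / N, np.sqrt(var_e / N))
        # v | mu, variances: independent normals in the eigenbasis
        prec = 1.0 / (w * var_u) + 1.0 / var_e
        mean = (yt - t * mu) / var_e / prec
        v = mean + rng.standard_normal(N) / np.sqrt(prec)
        # variances | rest: scaled inverse-chi-squared conjugate updates
        if fix_u is None:
            ss = np.sum(v**2 / w) + df_u * S_u
            # floor keeps the chain proper when the data carry no signal
            var_u = max(ss / rng.chisquare(N + df_u), 1e-12)
        if fix_e is None:
            resid = yt - t * mu - v
            ss = resid @ resid + df_e * S_e
            var_e = max(ss / rng.chisquare(N + df_e), 1e-12)
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            keep["mu"].append(mu)
            keep["var_u"].append(var_u)
            keep["var_e"].append(var_e)
            keep["v"].append(v.copy())

    samples = {k: np.asarray(s) for k, s in keep.items()}
    u_mean = U @ samples["v"].mean(axis=0)
    ess = {k: _ess(samples[k]) for k in ("mu", "var_u", "var_e")}
    low = {k: e for k, e in ess.items() if e < spec.ess_floor}
    if low:
        warnings.warn(
            f"effective sample size below {spec.ess_floor}: {low}; "
            "consider a longer chain",
            stacklevel=2,
        )
    return GblupFit(
        mu=float(samples["mu"].mean()),
        u=u_mean,
        var_u=float(samples["var_u"].mean()),
        var_e=float(samples["var_e"].mean()),
        ess=ess,
        samples=samples,
    )
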