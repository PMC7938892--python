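"""Nested cross-validation benchmark of (filter x subset size x learner).

An outer 10-fold split estimates generalization (Spearman correlation of
observed vs. predicted adjusted RFI on each held-out fold); within each
outer training set an inner 6-fold split tunes hyper-parameters.  Feature
standardization, filter scores and tuning all derive from outer-training
data only, and every configuration consumes the same split object.
"""

from __future__ import annotations

import hashlib
import logging
import traceback
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import filters as flt
from .containers import FilterScore, GenotypeMatrix
from .learners import (
    GblupSpec,
    GbSpec,
    PenalizedRegSpec,
    SvmSpec,
    compute_grm,
    fit_gblup_gibbs,
    fit_gradient_boosting,
    fit_penalized_regression,
    fit_svm_rbf,
    standardize_features,
)

__all__ = [
    "CVSplit",
    "ExperimentConfig",
    "ExperimentResult",
    "make_nested_splits",
    "run_experiment",
    "summarize_accuracy",
]

log = logging.getLogger(__name__)

FILTER_NAMES = ("spearcor", "univ.dtree", "mrmr", "cforest", "random", "none")
LEARNER_NAMES = ("enet", "lasso", "ridge", "svm", "gb", "gblup", "mean")
EMBEDDED = ("enet", "lasso")


@dataclass
class CVSplit:
    """Shared nested split: 1-based outer fold per animal, and per outer
    fold a 1-based inner fold per training animal (0 marks the held-out
    test animals)."""

    outer_assignments: np.ndarray
    inner_assignments: dict
    seed: int

    @property
    def n_outer(self) -> int:
        return int(self.outer_assignments.max())


def make_nested_splits(
    animal_ids: Sequence, outer: int = 10, inner: int = 6, seed: int = 0
) -> CVSplit:
    """Seeded random nested partition; fold sizes differ by at most 1."""
    n = len(animal_ids)
    if n < outer * inner:
        raise ValueError(f"need N >= {outer * inner} animals")
    rng = np.random.default_rng(seed)

    def assign(size: int, k: int, r) -> np.ndarray:
        lab = np.arange(size) % k + 1
        return r.permutation(lab)

    outer_assign = assign(n, outer, rng)
    inner_assign = {}
    for f in range(1, outer + 1):
        train = np.where(outer_assign != f)[0]
        lab = np.zeros(n, dtype=int)
        lab[train] = assign(len(train), inner, rng)
        inner_assign[f] = lab
    return CVSplit(outer_assign, inner_assign, seed)


@dataclass
class ExperimentConfig:
    filters: Sequence[str] = ("spearcor",)
    sizes: Sequence = (50,)               # ints and/or "all"
    learners: Sequence[str] = ("ridge",)
    outer_folds: int = 10
    inner_folds: int = 6
    seed: int = 0
    filter_params: dict = field(default_factory=dict)   # per filter name
    learner_specs: dict = field(default_factory=dict)   # per learner name

    def validate(self) -> None:
        for f in self.filters:
            if f not in FILTER_NAMES:
                raise ValueError(f"unknown filter {f!r}")
        for m in self.learners:
            if m not in LEARNER_NAMES:
                raise ValueError(f"unknown learner {m!r}")
        for s in self.sizes:
            if s != "all" and (not isinstance(s, (int, np.integer)) or s < 1):
                raise ValueError(f"bad subset size {s!r}")


@dataclass
class ExperimentResult:
    records: pd.DataFrame           # filter, size, learner, fold, sc, ...
    subsets: dict                   # (filter, size, origin) -> list per fold
    filter_scores: dict             # filter -> list of FilterScore per fold
    split: CVSplit
    fingerprints: dict              # (filter, size, learner) -> list per fold

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, grp in self.records.groupby(["filter", "size", "learner"]):
            sc = grp.loc[~grp["failed"], "sc"].to_numpy(float)
            sc = sc[~np.isnan(sc)]
            med, iqr = summarize_accuracy(sc) if len(sc) >= 2 else (np.nan, np.nan)
            rows.append(
                {
                    "filter": key[0],
                    "size": key[1],
                    "learner": key[2],
                    "median_sc": med,
                    "iqr_sc": iqr,
                    "n_folds": len(sc),
                    "n_failed": int(grp["failed"].sum()),
                }
            )
        return pd.DataFrame(rows)


def summarize_accuracy(per_fold_sc: Sequence[float]) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1, linear-interpolation
    quantiles) of the per-fold Spearman correlations; NaN folds (failed
    configurations) are ignored."""
    sc = np.asarray(per_fold_sc, dtype=float)
    sc = sc[~np.isnan(sc)]
    if len(sc) < 2:
        raise ValueError("need at least 2 folds")
    q1, med, q3 = np.percentile(sc, [25, 50, 75])
    return float(med), float(q3 - q1)


def _fingerprint(subset, params, vec) -> str:
    h = hashlib.sha256()
    h.update(repr(sorted(map(str, subset))).encode())
    h.update(repr(sorted(params.items())).encode())
    if vec is not None:
        h.update(np.ascontiguousarray(np.asarray(vec, dtype=float)).tobytes())
    return h.hexdigest()


def _run_filter(name, X_train, y_train, size, seed, params) -> tuple[FilterScore | None, list]:
    snp_ids = list(X_train.columns)
    p = len(snp_ids)
    k = p if size == "all" else int(size)
    if name == "none":
        return None, snp_ids
    if name == "random":
        return None, flt.select_random(snp_ids, k, seed=seed)
    if name == "spearcor":
        score = flt.score_spearcor(X_train, y_train)
    elif name == "univ.dtree":
        score = flt.score_univ_dtree(X_train, y_train, seed=seed, **params)
    elif name == "mrmr":
        score, selected = flt.score_mrmr(X_train, y_train, k=k, **params)
        return score, selected
    elif name == "cforest":
        score = flt.score_cforest_cpi(X_train, y_train, seed=seed, **params)
    else:
        raise ValueError(name)
    return score, flt.select_top_k(score, k)


def _fit_learner(name, X_train, y_train, inner, seed, spec):
    if name == "mean":  # constant-predictor stub (benchmark/testing)
        mu = float(np.mean(y_train))

        class _Mean:
            best_params: dict = {}
            selected_snps = None
            importance = None

            @staticmethod
            def predict(X):
                return np.full(np.asarray(X).shape[0], mu)

        return _Mean()
    if name == "enet":
        return fit_penalized_regression(
            X_train, y_train, spec or PenalizedRegSpec(), inner_cv=inner
        )
    if name == "lasso":
        return fit_penalized_regression(
            X_train, y_train, spec or PenalizedRegSpec(alpha_grid=(1.0,)),
            inner_cv=inner,
        )
    if name == "ridge":
        return fit_penalized_regression(
            X_train, y_train, spec or PenalizedRegSpec(alpha_grid=(0.0,)),
            inner_cv=inner,
        )
    if name == "svm":
        return fit_svm_rbf(X_train, y_train, spec or SvmSpec(), inner_cv=inner)
    if name == "gb":
        return fit_gradient_boosting(
            X_train, y_train, spec or GbSpec(), inner_cv=inner, seed=seed
        )
    raise ValueError(name)


def run_experiment(
    config: ExperimentConfig, geno: GenotypeMatrix, pheno: pd.Series
) -> ExperimentResult:
    """Run the full nested-CV benchmark.

    ``pheno`` is the adjusted RFI indexed by animal_id; only animals
    present in both inputs are used.  For each outer fold: standardize on
    the training block, score each filter on training data, select each
    subset size, tune each learner on the inner folds, refit on the full
    outer-training set and predict the held-out animals.  A failing
    configuration (e.g. the SVM/GB feature cap at full panel width) is
    recorded as failed; the rest continue.
    """
    config.validate()
    ids = [a for a in pheno.index if a in set(geno.samples)]
    X_all = geno.values.loc[ids]
    y_all = pheno.loc[ids].to_numpy(dtype=float)
    split = make_nested_splits(
        ids, outer=config.outer_folds, inner=config.inner_folds, seed=config.seed
    )

    needs_gblup = "gblup" in config.learners
    G = compute_grm(X_all.to_numpy()) if needs_gblup else None

    records: list[dict] = []
    subsets: dict = {}
    fingerprints: dict = {}
    gblup_cache: dict = {}
    filter_scores: dict = {f: [] for f in config.filters if f not in ("random", "none")}

    for fold in range(1, config.outer_folds + 1):
        tr = np.where(split.outer_assignments != fold)[0]
        te = np.where(split.outer_assignments == fold)[0]
        inner = split.inner_assignments[fold][tr]
        Xtr_s, Xte_s, _, _ = standardize_features(
            X_all.iloc[tr], X_all.iloc[te]
        )
        ytr, yte = y_all[tr], y_all[te]
        fold_seed = config.seed * 1000 + fold

        for fname in config.filters:
            try:
                score, selected = _run_filter(
                    fname, Xtr_s, ytr, max(
                        [s for s in config.sizes if s != "all"], default="all"
                    ),
                    fold_seed, config.filter_params.get(fname, {}),
                )
            except Exception:
                log.error("filter %s failed on fold %d:\n%s", fname, fold,
                          traceback.format_exc())
                for size in config.sizes:
                    for lname in config.learners:
                        records.append(_failed_rec(fname, size, lname, fold))
                continue
            if score is not None:
                filter_scores[fname].append(score)

            for size in config.sizes:
                if size == "all" or fname == "none":
                    sel = list(Xtr_s.columns)
                elif fname == "random":
                    sel = flt.select_random(list(Xtr_s.columns), int(size),
                                            seed=fold_seed)
                elif fname == "mrmr":
                    sel = selected[: int(size)]
                else:
                    sel = flt.select_top_k(score, int(size))
                subsets.setdefault((fname, size, "filter"), []).append(sel)

                for lname in config.learners:
                    key = (fname, size, lname)
                    try:
                        if lname == "gblup":
                            # GBLUP ignores the selected subset (benchmark
                            # without selection): fit once per fold
                            if fold not in gblup_cache:
                                gblup_cache[fold] = _run_gblup_fold(
                                    config, G, y_all, tr, te, fold_seed
                                )
                            rec, fp = gblup_cache[fold]
                        else:
                            spec = config.learner_specs.get(lname)
                            model = _fit_learner(
                                lname, Xtr_s[sel], ytr, inner, fold_seed, spec
                            )
                            pred = model.predict(Xte_s[sel])
                            # constant predictions carry no ranking
                            # information: score 0 rather than undefined
                            if np.ptp(pred) == 0:
                                sc = 0.0
                            else:
                                sc = stats.spearmanr(yte, pred).statistic
                            rec = {
                                "sc": float(sc),
                                "n_selected": (
                                    len(model.selected_snps)
                                    if model.selected_snps is not None
                                    else len(sel)
                                ),
                            }
                            fp = _fingerprint(
                                model.selected_snps or sel,
                                model.best_params,
                                model.predict(Xtr_s[sel]),
                            )
                            if lname in EMBEDDED:
                                subsets.setdefault(
                                    (fname, size, lname), []
                                ).append(list(model.selected_snps))
                    except Exception:
                        log.error("config %s failed on fold %d:\n%s", key,
                                  fold, traceback.format_exc())
                        records.append(_failed_rec(fname, size, lname, fold))
                        continue
                    records.append(
                        {"filter": fname, "size": size, "learner": lname,
                         "fold": fold, "failed": False, **rec}
                    )
                    fingerprints.setdefault(key, []).append(fp)

    return ExperimentResult(
        records=pd.DataFrame(records),
        subsets=subsets,
        filter_scores=filter_scores,
        split=split,
        fingerprints=fingerprints,
    )


def _failed_rec(fname, size, lname, fold) -> dict:
    return {"filter": fname, "size": size, "learner": lname, "fold": fold,
            "failed": True, "sc": np.nan, "n_selected": 0}


def _run_gblup_fold(config, G, y_all, tr, te, fold_seed):
    import dataclasses

    spec = config.learner_specs.get("gblup") or GblupSpec()
    spec = dataclasses.replace(spec, seed=fold_seed)
    fit = fit_gblup_gibbs(y_all[tr], G[np.ix_(tr, tr)], spec)
    fit.G = G
    fit.train_index = tr
    pred = fit.predict(te)
    sc = stats.spearmanr(y_all[te], pred).statistic
    fp = _fingerprint([], {"var_u": fit.var_u, "var_e": fit.var_e}, fit.u)
    return {"sc": float(sc), "n_selected": G.shape[0]}, fp
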