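"""Feature-selection stability estimation.

Quantifies how sensitive a feature-selection procedure is to perturbation
of its training data, given the subsets it selected on ``n`` different
training sets drawn from the same ``p``-feature universe.

The central quantity is the chance-corrected stability estimator of
Nogueira and co-workers ("NOG"),

    phi_hat = 1 - (1/p) * sum_i sigma2_i / (dbar/p * (1 - dbar/p)),

where ``sigma2_i = n/(n-1) * phat_i * (1 - phat_i)`` is the unbiased sample
variance of the selection indicator of feature ``i`` (``phat_i`` its
selection frequency) and ``dbar`` the mean subset size.  The denominator is
the expected numerator under uniform random selection of ``dbar`` features,
so phi_hat has expectation 0 for a random selector and equals 1 exactly
when all subsets are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FeatureSubsetSystem",
    "StabilityReport",
    "nog_stability",
    "nog_confidence_interval",
    "subset_descriptives",
    "score_stability",
    "expected_random_pdf",
    "random_subset_system",
    "stability_report",
]


@dataclass
class FeatureSubsetSystem:
    """A system of n > 1 feature subsets selected from a p-feature universe.

    Parameters
    ----------
    universe : sequence of feature IDs (the p features available to the
        selector), or an integer p meaning features ``0..p-1``.
    subsets : n lists of selected feature IDs, one per selection run
        (e.g. one per outer training fold).  Sizes may differ.
    """

    universe: Sequence
    subsets: Sequence[Sequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.universe, (int, np.integer)):
            self.universe = np.arange(int(self.universe))
        self.universe = np.asarray(self.universe)
        if len(set(map(str, self.universe))) != len(self.universe):
            raise ValueError("feature universe contains duplicate IDs")
        index = {f: i for i, f in enumerate(self.universe)}
        self.subsets = [list(s) for s in self.subsets]
        for s in self.subsets:
            for f in s:
                if f not in index:
                    raise ValueError(f"subset feature {f!r} not in universe")
        self._index = index

    @property
    def p(self) -> int:
        return len(self.universe)

    @property
    def n(self) -> int:
        return len(self.subsets)

    @property
    def sizes(self) -> np.ndarray:
        """Subset sizes d_j."""
        return np.array([len(s) for s in self.subsets])

    def indicator_matrix(self) -> np.ndarray:
        """n x p binary matrix Z with Z[j, i] = 1 iff feature i in subset j."""
        Z = np.zeros((self.n, self.p), dtype=float)
        for j, s in enumerate(self.subsets):
            for f in s:
                Z[j, self._index[f]] = 1.0
        return Z


@dataclass
class StabilityReport:
    nog: float
    ci: tuple[float, float]
    nsnps_total: int
    pdf: float
    median_sel: float
    iqr_sel: float
    pearson_score_stab: float | None = None
    spearman_score_stab: float | None = None


def _nog_from_indicator(Z: np.ndarray) -> float:
    n, p = Z.shape
    phat = Z.mean(axis=0)
    dbar = phat.sum()
    if dbar <= 0 or dbar >= p:
        raise ValueError(
            "NOG is undefined when the mean subset size is 0 or p "
            f"(got dbar={dbar}, p={p})"
        )
    sigma2 = n / (n - 1) * phat * (1.0 - phat)
    return 1.0 - sigma2.mean() / (dbar / p * (1.0 - dbar / p))


def nog_stability(system: FeatureSubsetSystem) -> float:
    """Chance-corrected stability phi_hat of a subset system.

    Equals 1 iff all subsets are identical; has expectation 0 under
    uniform random selection.  Requires n > 1 and 0 < mean subset size < p.
    """
    if system.n < 2:
        raise ValueError("stability requires n > 1 subsets")
    return _nog_from_indicator(system.indicator_matrix())


def nog_confidence_interval(
    system: FeatureSubsetSystem, alpha: float = 0.05
) -> tuple[float, float]:
    """Asymptotic-normal confidence interval for the population stability.

    Uses the delta-method variance of the chance-corrected estimator: each
    subset contributes an influence term

        phi_j = (1/den) * [ mean_i(Z_ji * phat_i) - d_j*dbar/p^2
                 + (phi_hat/2) * (2*d_j*dbar/p^2 - d_j/p - dbar/p + 1) ],

    with den = dbar/p (1 - dbar/p), and Var(phi_hat) is estimated by
    (4/n^2) * sum_j (phi_j - mean(phi))^2.  The interval is
    phi_hat +/- z_{1-alpha/2} * SE.  Degenerate systems (all subsets
    identical) give a zero-width interval.
    """
    if system.n < 2:
        raise ValueError("confidence interval requires n > 1 subsets")
    Z = system.indicator_matrix()
    n, p = Z.shape
    stab = _nog_from_indicator(Z)
    if stab == 1.0:  # identical subsets: degenerate, zero-width interval
        return (1.0, 1.0)
    phat = Z.mean(axis=0)
    dbar = phat.sum()
    den = dbar / p * (1.0 - dbar / p)
    d = Z.sum(axis=1)
    phi = (1.0 / den) * (
        (Z * phat).mean(axis=1)
        - d * dbar / p**2
        + (stab / 2.0) * (2.0 * d * dbar / p**2 - d / p - dbar / p + 1.0)
    )
    var = 4.0 / n**2 * np.sum((phi - phi.mean()) ** 2)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (stab - half, stab + half)


def subset_descriptives(
    system: FeatureSubsetSystem,
) -> tuple[int, float, float, float]:
    """Descriptive statistics of a subset system.

    Returns ``(NSNPs, PDF, medianSel, IQRSel)``: the total number of
    selections summed over subsets, the proportion of distinct features
    among those selections (1/n for identical subsets, ~1 for disjoint
    ones), and the median and interquartile range of the subset sizes.
    """
    if system.n < 1:
        raise ValueError("need at least one subset")
    sizes = system.sizes
    nsnps = int(sizes.sum())
    if nsnps == 0:
        raise ValueError("all subsets are empty")
    distinct = len(set().union(*map(set, system.subsets)))
    pdf = distinct / nsnps
    q1, med, q3 = np.percentile(sizes, [25, 50, 75])
    return nsnps, pdf, float(med), float(q3 - q1)


def score_stability(
    scores: Sequence[np.ndarray],
) -> tuple[float, float]:
    """Score-based stability of a filter across n training sets.

    ``scores`` is a sequence of n per-feature relevance vectors over the
    same feature universe (same order).  Returns the mean Pearson
    correlation of the raw scores and the mean Spearman correlation of
    the ranks over all n(n-1)/2 pairs.  Pairs involving a constant score
    vector are excluded with a warning.
    """
    vecs = [np.asarray(s, dtype=float) for s in scores]
    if len({len(v) for v in vecs}) != 1:
        raise ValueError("score vectors cover different universes")
    pcs, scs = [], []
    for a in range(len(vecs)):
        for b in range(a + 1, len(vecs)):
            if np.std(vecs[a]) == 0 or np.std(vecs[b]) == 0:
                warnings.warn(
                    f"constant score vector in pair ({a}, {b}); pair excluded",
                    stacklevel=2,
                )
                continue
            pcs.append(stats.pearsonr(vecs[a], vecs[b]).statistic)
            scs.append(stats.spearmanr(vecs[a], vecs[b]).statistic)
    if not pcs:
        raise ValueError("no non-degenerate score pairs")
    return float(np.mean(pcs)), float(np.mean(scs))


def expected_random_pdf(p: int, d: int, n: int) -> float:
    """Expected proportion of distinct features for uniform random subsets.

    For n independent uniform subsets of size d drawn without replacement
    from p features, the expected number of distinct selected features is
    p * (1 - ((p-d)/p)^n), so the expected PDF is that divided by n*d.
    """
    if not 0 < d <= p:
        raise ValueError("need 0 < d <= p")
    return p * (1.0 - ((p - d) / p) ** n) / (n * d)


def random_subset_system(
    p: int, d: int, n: int, rng: np.random.Generator
) -> FeatureSubsetSystem:
    """Draw n uniform random subsets of size d from a p-feature universe."""
    subsets = [rng.choice(p, size=d, replace=False) for _ in range(n)]
    return FeatureSubsetSystem(universe=p, subsets=subsets)


def stability_report(
    system: FeatureSubsetSystem,
    scores: Sequence[np.ndarray] | None = None,
    alpha: float = 0.05,
) -> StabilityReport:
    """Full stability report for one (filter, size, learner) configuration."""
    nsnps, pdf, med, iqr = subset_descriptives(system)
    nog = nog_stability(system)
    ci = nog_confidence_interval(system, alpha=alpha)
    pc = sc = None
    if scores is not None:
        pc, sc = score_stability(scores)
    return StabilityReport(
        nog=nog,
        ci=ci,
        nsnps_total=nsnps,
        pdf=pdf,
        median_sel=med,
        iqr_sel=iqr,
        pearson_score_stab=pc,
        spearman_score_stab=sc,
    )
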