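"""Filter methods: relevance semantics, redundancy handling, determinism,
and agreement between the Gaussian and plug-in MI routes."""

import numpy as np
import pytest
from scipy import stats

from fsstab.containers import FilterScore
from fsstab.filters import (
    gaussian_mi,
    plugin_mi,
    score_cforest_cpi,
    score_mrmr,
    score_spearcor,
    score_univ_dtree,
    select_random,
    select_top_k,
)


class TestSpearcor:
    def test_target_equal_to_feature_scores_one(self, rng):
        X = rng.standard_normal((200, 5))
        fs = score_spearcor(X, X[:, 3])
        assert fs.scores[3] == pytest.approx(1.0)
        assert fs.ranks[3] == 1

    def test_monotone_nonlinear_target_still_scores_one(self, rng):
        X = rng.standard_normal((200, 4))
        fs = score_spearcor(X, np.exp(X[:, 1]))
        assert fs.scores[1] == pytest.approx(1.0)

    def test_null_scores_stay_small(self, rng):
        X = rng.standard_normal((1000, 50))
        fs = score_spearcor(X, rng.standard_normal(1000))
        assert fs.scores.max() < 0.15

    def test_constant_column_scores_zero_with_warning(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        with pytest.warns(UserWarning, match="constant"):
            fs = score_spearcor(X, rng.standard_normal(50))
        assert fs.scores[0] == 0.0

    def test_matches_scipy_per_column(self, rng):
        X = rng.integers(0, 3, (150, 6)).astype(float)
        y = rng.standard_normal(150)
        fs = score_spearcor(X, y)
        for j in range(6):
            ref = abs(stats.spearmanr(X[:, j], y).statistic)
            assert fs.scores[j] == pytest.approx(ref, abs=1e-12)


class TestUnivDtree:
    def test_step_function_target_is_top_ranked(self, rng):
        X = rng.standard_normal((200, 6))
        y = np.where(X[:, 2] > 0, 5.0, -5.0)
        fs = score_univ_dtree(X, y, seed=0)
        assert np.argmax(fs.scores) == 2
        assert fs.scores[2] == pytest.approx(0.0, abs=1e-6)  # -CV MSE ~ 0

    def test_noise_feature_scores_near_minus_var(self, rng):
        X = rng.standard_normal((500, 1))
        y = rng.standard_normal(500)
        fs = score_univ_dtree(X, y, seed=0)
        # a tree on pure noise predicts ~fold means: score ~ -var(y)
        assert fs.scores[0] == pytest.approx(-np.var(y), rel=0.25)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((100, 5))
        y = rng.standard_normal(100)
        a = score_univ_dtree(X, y, seed=7)
        b = score_univ_dtree(X, y, seed=7)
        assert np.array_equal(a.scores, b.scores)


class TestMrmr:
    def test_first_pick_is_max_marginal_mi(self, rng):
        X = rng.standard_normal((300, 8))
        y = 2.0 * X[:, 5] + rng.standard_normal(300)
        score, sel = score_mrmr(X, y, k=3)
        rhos = [abs(stats.pearsonr(X[:, j], y).statistic) for j in range(8)]
        assert sel[0] == int(np.argmax(rhos))

    def test_exact_copy_deferred_behind_weak_independent_signal(self, rng):
        n = 500
        x1 = rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        y = x1 + 0.3 * x3 + 0.5 * rng.standard_normal(n)
        X = np.column_stack([x1, x1.copy(), x3])
        _, sel = score_mrmr(X, y, k=2)
        assert sel[0] in (0, 1)
        assert sel[1] == 2  # the copy is infinitely redundant

    def test_k_equal_p_selects_everything_deterministically(self, rng):
        X = rng.standard_normal((100, 6))
        y = rng.standard_normal(100)
        _, sel_a = score_mrmr(X, y, k=6)
        _, sel_b = score_mrmr(X, y, k=6)
        assert sel_a == sel_b and sorted(sel_a) == list(range(6))

    def test_selection_order_encoded_in_ranks(self, rng):
        X = rng.standard_normal((100, 5))
        y = X[:, 0] + rng.standard_normal(100)
        score, sel = score_mrmr(X, y, k=3)
        assert select_top_k(score, 3) == sel

    def test_gaussian_and_plugin_agree_on_top_feature(self, rng):
        X = rng.standard_normal((600, 6))
        y = 1.5 * X[:, 2] + rng.standard_normal(600)
        _, sel_g = score_mrmr(X, y, k=1, mi_estimator="gaussian")
        _, sel_p = score_mrmr(X, y, k=1, mi_estimator="plugin")
        assert sel_g[0] == sel_p[0] == 2

    def test_plugin_mi_close_to_analytic_gaussian_value(self, rng):
        rho = 0.8
        n = 60_000
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        analytic = float(gaussian_mi(np.array([rho]))[0])
        est = plugin_mi(x, y, bins=8)
        assert est == pytest.approx(analytic, rel=0.2)


class TestCforest:
    def test_unused_feature_scores_exactly_zero(self, rng):
        X = np.column_stack(
            [rng.integers(0, 3, 200).astype(float), np.full(200, 1.0)]
        )
        fs = score_cforest_cpi(X, rng.standard_normal(200), n_trees=30, seed=0)
        assert fs.scores[1] == 0.0

    def test_strong_qtl_gets_top_score_across_seeds(self, rng):
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            X = r.integers(0, 3, (250, 10)).astype(float)
            y = 2.0 * X[:, 4] + r.standard_normal(250)
            fs = score_cforest_cpi(X, y, n_trees=60, seed=seed)
            wins += int(np.argmax(fs.scores) == 4)
        assert wins >= 9

    def test_null_target_scores_center_on_zero(self, rng):
        means = []
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            X = r.integers(0, 3, (150, 8)).astype(float)
            fs = score_cforest_cpi(X, r.standard_normal(150), n_trees=40,
                                   seed=seed)
            means.append(fs.scores.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * se + 0.02

    def test_few_trees_warns(self, rng):
        X = rng.integers(0, 3, (60, 4)).astype(float)
        with pytest.warns(UserWarning, match="unstable"):
            score_cforest_cpi(X, rng.standard_normal(60), n_trees=5, seed=0)

    def test_deterministic_given_seed(self, rng):
        X = rng.integers(0, 3, (120, 6)).astype(float)
        y = rng.standard_normal(120)
        a = score_cforest_cpi(X, y, n_trees=25, seed=3)
        b = score_cforest_cpi(X, y, n_trees=25, seed=3)
        assert np.array_equal(a.scores, b.scores)


class TestSelection:
    def test_random_full_and_empty(self):
        ids = [f"s{j}" for j in range(20)]
        assert set(select_random(ids, 20, seed=1)) == set(ids)
        assert select_random(ids, 0, seed=1) == []

    def test_random_deterministic_and_overlap_near_hypergeometric(self):
        ids = list(range(400))
        a = select_random(ids, 80, seed=5)
        assert a == select_random(ids, 80, seed=5)
        overlaps = [
            len(set(select_random(ids, 80, seed=2 * s))
                & set(select_random(ids, 80, seed=2 * s + 1)))
            for s in range(40)
        ]
        assert np.mean(overlaps) == pytest.approx(80**2 / 400, rel=0.15)

    def test_top_k_rules(self, rng):
        ids = [f"s{j}" for j in range(10)]
        fs = FilterScore("t", ids, np.arange(10)[::-1])  # descending scores
        assert select_top_k(fs, 3) == ["s0", "s1", "s2"]
        rev = FilterScore("t", ids, np.arange(10))  # ascending scores
        assert select_top_k(rev, 2) == ["s9", "s8"]
        ties = FilterScore("t", ids, np.zeros(10))
        assert select_top_k(ties, 4) == ids[:4]  # index tie-break
        assert select_top_k(fs, 10) == ids
        with pytest.raises(ValueError, match="exceeds"):
            select_top_k(fs, 11)


def test_spearcor_and_mrmr_agree_on_top1_for_independent_snps(rng):
    # with mutually independent features Gaussian MI is monotone in |rho|
    X = rng.integers(0, 3, (800, 12)).astype(float)
    y = 1.2 * X[:, 7] + rng.standard_normal(800)
    top_spear = select_top_k(score_spearcor(X, y), 1)
    _, top_mrmr = score_mrmr(X, y, k=1)
    assert top_spear[0] == top_mrmr[0] == 7
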