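"""Filter statistics: hand-computed oracles, cross-library identities,
MIC exhaustive-vs-DP agreement, and ranking determinism."""
import math

import numpy as np
import pytest
import scipy.stats

import coresnp as cs
from coresnp.feature_scoring import MicConfig

from conftest import random_two_class_fixture


class TestAnovaF:
    def test_hand_example(self):
        # between SS = 1 (df 1), within SS = 4 (df 2) -> F = 0.5
        x = np.array([0.0, 2.0, 1.0, 3.0])
        levels = np.array([0, 0, 1, 1])
        assert cs.anova_f(x, levels) == pytest.approx(0.5)

    def test_equal_group_means_zero(self):
        x = np.array([0.0, 2.0, 2.0, 0.0])
        assert cs.anova_f(x, np.array([0, 0, 1, 1])) == 0.0

    def test_constant_feature_zero(self):
        assert cs.anova_f(np.ones(6), np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_perfect_separation_is_inf(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert cs.anova_f(x, np.array([0, 0, 1, 1])) == math.inf

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x, labels = random_two_class_fixture(rng)
            expected = scipy.stats.f_oneway(x[labels == 0], x[labels == 1]).statistic
            assert cs.anova_f(x, labels) == pytest.approx(expected)

    def test_two_class_equals_squared_t(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x, labels = random_two_class_fixture(rng)
            t = scipy.stats.ttest_ind(x[labels == 0], x[labels == 1]).statistic
            assert cs.anova_f(x, labels) == pytest.approx(t * t)

    def test_quantitative_matches_sklearn_f_regression(self):
        from sklearn.feature_selection import f_regression

        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, (50, 8)).astype(float)
        y = rng.normal(size=50)
        expected = f_regression(X, y)[0]
        got = [cs.anova_f(X[:, j], y, mode="quantitative") for j in range(8)]
        assert got == pytest.approx(expected.tolist())

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            cs.anova_f(np.array([0.0, 1.0]), np.array([0, 0]))


class TestFisherScore:
    def test_hand_example(self):
        x = np.array([0.0, 2.0, 1.0, 3.0])
        assert cs.fisher_score(x, np.array([0, 0, 1, 1])) == pytest.approx(0.25)

    def test_identical_classes_zero(self):
        assert cs.fisher_score(np.ones(4), np.array([0, 0, 1, 1])) == 0.0

    def test_separable_sentinel_magnitude(self):
        from coresnp.feature_scoring import FISHER_EPS

        # zero within-class scatter: score collapses to numerator / eps
        x = np.array([0.0, 0.0, 1.0, 1.0])
        score = cs.fisher_score(x, np.array([0, 0, 1, 1]))
        assert score == pytest.approx(1.0 / FISHER_EPS, rel=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x, labels = random_two_class_fixture(rng)
            base = cs.fisher_score(x, labels)
            trans = cs.fisher_score(3.5 * x - 7.0, labels)
            assert trans == pytest.approx(base, rel=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.fisher_score(np.array([0.0, 1.0]), np.array([1, 1]))


class TestMic:
    def test_perfect_two_block_association(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert cs.mic_oracle(x, x) == pytest.approx(1.0)

    def test_constant_variable_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cs.mic_oracle(x, np.ones(4)) == 0.0

    def test_monotone_bijection_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert cs.mic_oracle(x, -x) == pytest.approx(1.0)

    def test_oracle_rejects_large_n(self):
        with pytest.raises(ValueError, match="approximate"):
            cs.mic_oracle(np.arange(100.0), np.arange(100.0))

    def test_score_equals_oracle_small_n(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(4, 31))
            x = rng.integers(0, 3, n).astype(float)
            y = rng.normal(size=n) if trial % 2 else rng.integers(1, 4, n).astype(float)
            assert cs.mic_score(x, y) == pytest.approx(cs.mic_oracle(x, y))

    def test_dp_never_exceeds_oracle(self):
        rng = np.random.default_rng(6)
        cfg = MicConfig(mode="approximate")
        for _ in range(30):
            n = int(rng.integers(5, 26))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert cs.mic_score(x, y, cfg) <= cs.mic_oracle(x, y) + 1e-9

    def test_signal_beats_permutation(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 3, 200).astype(float)
        y = x + rng.normal(scale=0.3, size=200)
        assert cs.mic_score(x, y) > cs.mic_score(x, rng.permutation(y))

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(8)
        for n in (20, 120):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            a, b = cs.mic_score(x, y), cs.mic_score(y, x)
            assert a == b
            assert 0.0 <= a <= 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 3, 150).astype(float)
        y = x + rng.normal(scale=0.5, size=150)
        base = cs.mic_score(x, y)
        assert cs.mic_score(x, np.exp(y)) == pytest.approx(base, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cs.mic_score(np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0]))


class TestRankFeatures:
    def test_causal_recovery_in_top_ranks(self, sim_small):
        g, _, pheno, truth = sim_small
        table = cs.rank_features(g, pheno, "anova", "quantitative")
        assert cs.planted_recovery_rate(table, truth.causal_ids, 30) == 1.0

    def test_identical_columns_tie_broken_by_order(self):
        X = np.array([[0, 0, 1], [1, 1, 0], [2, 2, 2], [0, 0, 1]])
        levels = np.array([1, 1, 2, 2])
        table = cs.rank_features(X, levels, "fscore", "categorical")
        assert table.scores[0] == table.scores[1]
        assert table.ranks[0] < table.ranks[1]

    def test_single_snp(self):
        table = cs.rank_features(
            np.array([[0], [1], [2], [0]]), np.array([1, 1, 2, 2]), "anova"
        )
        assert len(table) == 1 and table.ranks.tolist() == [1]

    def test_pure_function(self, sim_small):
        g, _, pheno, _ = sim_small
        a = cs.rank_features(g, pheno, "fscore", "categorical")
        b = cs.rank_features(g, pheno, "fscore", "categorical")
        assert (a.ranks == b.ranks).all() and (a.scores == b.scores).all()

    def test_ranks_are_permutation_and_top_is_max(self, sim_small):
        g, _, pheno, _ = sim_small
        table = cs.rank_features(g, pheno, "anova", "categorical")
        assert sorted(table.ranks) == list(range(1, len(table) + 1))
        assert table.scores[np.argmin(table.ranks)] == table.scores.max()

    def test_misaligned_target_rejected(self, sim_small):
        g, _, _, _ = sim_small
        with pytest.raises(ValueError):
            cs.rank_features(g, np.array([1, 2, 3]), "anova")
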