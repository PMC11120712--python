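"""Imputation, quartile discretization, splitting and LD pruning."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coresnp as cs
from coresnp.io_formats import MISSING


def _gm(columns):
    X = np.array(columns).T.astype(np.int8)
    return cs.GenotypeMatrix(
        X, [f"s{i}" for i in range(X.shape[0])], [f"v{j}" for j in range(X.shape[1])]
    )


class TestImpute:
    def test_mode_fill(self):
        g = _gm([[0, 0, MISSING, 2]])
        assert cs.impute_missing(g).dosages[:, 0].tolist() == [0, 0, 0, 2]

    def test_all_missing_column_dropped(self):
        g = _gm([[MISSING] * 4, [0, 1, 2, 0]])
        out = cs.impute_missing(g)
        assert out.n_snps == 1 and out.snp_ids == ["v1"]

    def test_mode_tie_prefers_smaller_dosage(self):
        g = _gm([[0, 0, 2, 2, MISSING]])
        assert cs.impute_missing(g).dosages[4, 0] == 0


class TestDiscretize:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([10, 11, 12, 13, 14, 15, 16, 17], [1, 1, 2, 2, 2, 2, 3, 3]),
            ([4, 3, 2, 1], [3, 2, 2, 1]),
            # ties broken by input order under the stable sort
            ([5, 5, 5, 5, 6, 6, 7, 7], [1, 1, 2, 2, 2, 2, 3, 3]),
        ],
    )
    def test_level_assignment(self, values, expected):
        assert cs.quartile_levels(np.array(values, dtype=float)).tolist() == expected

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            cs.quartile_levels(np.array([1.0, 2.0, 3.0]))

    @given(st.integers(min_value=4, max_value=400), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_level_counts_property(self, n, seed):
        values = np.random.default_rng(seed).normal(size=n)
        levels = cs.quartile_levels(values)
        assert (levels == 1).sum() == n // 4
        assert (levels == 3).sum() == n - (3 * n) // 4
        assert (levels == 2).sum() == (3 * n) // 4 - n // 4

    def test_exact_quarters_when_divisible(self):
        levels = cs.quartile_levels(np.arange(100.0))
        assert [(levels == k).sum() for k in (1, 2, 3)] == [25, 50, 25]


class TestSplit:
    def test_printed_sizes_n2799(self):
        ids = [f"s{i}" for i in range(2799)]
        train, test = cs.split_train_test(ids, cs.SplitSpec(0.2, 0, False))
        assert (len(train), len(test)) == (2239, 560)

    def test_small_n(self):
        train, test = cs.split_train_test(
            [f"s{i}" for i in range(10)], cs.SplitSpec(0.2, 3, False)
        )
        assert (len(train), len(test)) == (8, 2)

    def test_partition_and_determinism(self):
        ids = [f"s{i}" for i in range(101)]
        spec = cs.SplitSpec(0.3, 7, False)
        a = cs.split_train_test(ids, spec)
        b = cs.split_train_test(ids, spec)
        assert a == b
        train, test = a
        assert sorted(train + test) == sorted(ids)
        assert not set(train) & set(test)

    def test_stratified_within_one_per_level(self):
        rng = np.random.default_rng(0)
        n = 2799
        levels = cs.quartile_levels(rng.normal(size=n))
        ids = [f"s{i}" for i in range(n)]
        train, test = cs.split_train_test(ids, cs.SplitSpec(0.2, 5, True), levels)
        assert len(test) == 560
        lv = dict(zip(ids, levels))
        for k in (1, 2, 3):
            n_k = (levels == k).sum()
            got = sum(1 for s in test if lv[s] == k)
            assert abs(got - 560 * n_k / n) <= 1

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            cs.split_train_test(["a", "b"], cs.SplitSpec(0.1, 0, False))


class TestGenotypeR2:
    def test_identical_and_flipped(self):
        x = np.array([0, 1, 2, 0])
        assert cs.genotype_r2(x, x) == pytest.approx(1.0)
        assert cs.genotype_r2(x, 2 - x) == pytest.approx(1.0)

    def test_hand_pearson_value(self):
        assert cs.genotype_r2(
            np.array([0, 1, 2, 0]), np.array([0, 1, 1, 1])
        ) == pytest.approx(3 / 11)

    def test_zero_variance_convention(self):
        assert cs.genotype_r2(np.array([1, 1, 1]), np.array([0, 1, 2])) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cs.genotype_r2(np.array([0, 1]), np.array([0, 1, 2]))


def _audit_no_window_pair_above(g, kept_ids, window, step, threshold):
    """Exhaustive check: no kept pair that co-occurs in any sliding window
    (single-chromosome instance) exceeds the r2 threshold."""
    idx = [g.snp_ids.index(k) for k in kept_ids]
    X = g.dosages.astype(float)
    for a, b in itertools.combinations(idx, 2):
        start = (a // step) * step  # last window start covering column a
        if b < start + window:
            assert cs.genotype_r2(X[:, a], X[:, b]) <= threshold + 1e-12


class TestLdPrune:
    def _simulated(self, p=30, n=150, seed=5, dup_pairs=((3, 4), (10, 11), (20, 21))):
        rng = np.random.default_rng(seed)
        X = rng.binomial(2, rng.uniform(0.2, 0.5, p), (n, p)).astype(np.int8)
        for a, b in dup_pairs:
            X[:, b] = X[:, a]
        meta = [cs.SnpMeta(f"v{j}", "chr01", (j + 1) * 10) for j in range(p)]
        g = cs.GenotypeMatrix(X, [f"s{i}" for i in range(n)], [f"v{j}" for j in range(p)])
        return g, meta

    def test_duplicate_column_removed(self):
        g, meta = self._simulated(p=6, dup_pairs=((0, 1),))
        kept = cs.ld_prune(g, meta, cs.PruneConfig(6, 3, 0.1))
        assert len({"v0", "v1"} & set(kept)) == 1

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(11)
        # orthogonal-ish large-n draw keeps every pairwise r2 below 0.1
        X = rng.binomial(2, 0.5, (4000, 12)).astype(np.int8)
        meta = [cs.SnpMeta(f"v{j}", "chr01", j + 1) for j in range(12)]
        g = cs.GenotypeMatrix(X, [f"s{i}" for i in range(4000)], [f"v{j}" for j in range(12)])
        kept = cs.ld_prune(g, meta, cs.PruneConfig(12, 6, 0.1))
        assert len(kept) == 12

    def test_planted_duplicates_audited(self):
        g, meta = self._simulated()
        cfg = cs.PruneConfig(10, 5, 0.1)
        kept = cs.ld_prune(g, meta, cfg)
        assert len(kept) <= 27  # 3 duplicate pairs each lose one member
        _audit_no_window_pair_above(g, kept, cfg.window, cfg.step, cfg.r2_threshold)

    def test_missing_rate_removal_preference(self):
        g, meta = self._simulated(p=6, dup_pairs=((0, 1),))
        rates = np.zeros(6)
        rates[1] = 0.3  # later duplicate is also the one with more missingness
        kept = cs.ld_prune(g, meta, cs.PruneConfig(6, 3, 0.1), rates)
        assert "v0" in kept and "v1" not in kept
        rates = np.zeros(6)
        rates[0] = 0.3  # now the earlier member must go
        kept = cs.ld_prune(g, meta, cs.PruneConfig(6, 3, 0.1), rates)
        assert "v1" in kept and "v0" not in kept

    def test_unsorted_meta_rejected(self):
        g, meta = self._simulated(p=6, dup_pairs=())
        meta[2], meta[3] = meta[3], meta[2]
        with pytest.raises(ValueError):
            cs.ld_prune(g, [meta[j] for j in range(6)], cs.PruneConfig(6, 3, 0.1))

    def test_exhaustive_audit_random_instances(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            p = 60
            base = rng.binomial(2, rng.uniform(0.1, 0.5, p), (120, p)).astype(np.int8)
            # smear some LD by copying neighbours with noise
            for j in range(1, p, 7):
                flip = rng.random(120) < 0.1
                base[:, j] = np.where(flip, base[:, j], base[:, j - 1])
            meta = [cs.SnpMeta(f"v{j}", "chr01", j + 1) for j in range(p)]
            g = cs.GenotypeMatrix(
                base, [f"s{i}" for i in range(120)], [f"v{j}" for j in range(p)]
            )
            cfg = cs.PruneConfig(20, 10, 0.1)
            kept = cs.ld_prune(g, meta, cfg)
            _audit_no_window_pair_above(g, kept, cfg.window, cfg.step, cfg.r2_threshold)
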