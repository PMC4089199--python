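import itertools
import math

import numpy as np
import pytest
import scipy.sparse as sp

from protsel import (
    class_statistics,
    final_metric,
    fit_selection,
    pairwise_metric,
    select_features,
)
from protsel.errors import DegenerateClassError, ParameterError, ShapeError
from protsel.selection import ClassStatistics, rank_features


def _naive_selection(matrix, labels, variant, n_total):
    """Pure-Python nested-loop oracle for the mean/variance/pair-metric/min
    pipeline, independent of the vectorized implementation."""
    matrix = np.asarray(matrix)
    classes = list(dict.fromkeys(labels))
    n_features = matrix.shape[1]
    means, variances, ns = {}, {}, {}
    for c in classes:
        rows = [matrix[i] for i, l in enumerate(labels) if l == c]
        ns[c] = len(rows)
        means[c] = [sum(r[j] for r in rows) / len(rows) for j in range(n_features)]
        variances[c] = [
            sum((means[c][j] - r[j]) ** 2 for r in rows) / (len(rows) - 1)
            for j in range(n_features)
        ]
    pair_rows = []
    for p, q in itertools.combinations(classes, 2):
        row = []
        for j in range(n_features):
            num = abs(means[p][j] - means[q][j])
            if variant == "as_printed":
                den = variances[p][j] / n_total + variances[q][j] / n_total
            else:
                den = math.sqrt(variances[p][j] / ns[p] + variances[q][j] / ns[q])
            if den == 0:
                row.append(0.0 if num == 0 else math.inf)
            else:
                row.append(num / den)
        pair_rows.append(row)
    return [min(r[j] for r in pair_rows) for j in range(n_features)]


class TestClassStatistics:
    def test_identical_vectors_zero_variance(self):
        m = np.array([[0.2, 0.5], [0.2, 0.5]])
        s = class_statistics(m, np.array(["a", "a"]), "a")
        assert np.allclose(s.mean, [0.2, 0.5])
        assert np.allclose(s.variance, 0.0)
        assert s.n_sequences == 2

    def test_worked_example_feature_m(self, sample_records, space3):
        """Mean/variance of the 'M' frequency over the five sample sequences
        matches a direct two-pass computation on the printed fractions."""
        from protsel import encode_dataset, LabeledDataset, ProteinSequence

        ds = LabeledDataset(classes=["demo", "pad"], sequences={
            "demo": sample_records,
            "pad": [ProteinSequence("p1", "WWW"), ProteinSequence("p2", "YYY")],
        })
        matrix, labels, _ = encode_dataset(ds, space3)
        stats = class_statistics(matrix, labels, "demo")
        fracs = [2 / 9, 2 / 8, 1 / 10, 2 / 8, 2 / 9]
        mean = sum(fracs) / 5
        var = sum((mean - f) ** 2 for f in fracs) / 4
        j = space3.index["M"]
        assert stats.mean[j] == pytest.approx(mean, rel=1e-12)
        assert stats.variance[j] == pytest.approx(var, rel=1e-12)

    def test_single_row_class_is_degenerate(self):
        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(DegenerateClassError, match="solo"):
            class_statistics(m, np.array(["solo", "other"]), "solo")

    def test_sparse_and_dense_agree(self, rng):
        dense = rng.random((8, 5))
        dense[dense < 0.5] = 0.0
        labels = np.array(["a"] * 4 + ["b"] * 4)
        s_dense = class_statistics(dense, labels, "a")
        s_sparse = class_statistics(sp.csr_matrix(dense), labels, "a")
        assert np.allclose(s_dense.mean, s_sparse.mean)
        assert np.allclose(s_dense.variance, s_sparse.variance)


def _stats(label, n, mean, var):
    return ClassStatistics(label, n, np.asarray(mean, float), np.asarray(var, float))


class TestPairwiseMetric:
    def test_hand_computed_toy_example_both_variants(self):
        # 3-sequence classes over 2 features, scalar arithmetic done by hand
        a = np.array([[0.1, 0.4], [0.2, 0.5], [0.3, 0.6]])
        b = np.array([[0.4, 0.4], [0.5, 0.5], [0.6, 0.6]])
        sa = class_statistics(np.vstack([a, b]), np.array(["a"] * 3 + ["b"] * 3), "a")
        sb = class_statistics(np.vstack([a, b]), np.array(["a"] * 3 + ["b"] * 3), "b")
        # both features have per-class sample variance 0.01; means differ by 0.3 / 0.0
        vd_printed = pairwise_metric(sa, sb, n_total=100, variant="as_printed")
        assert vd_printed[0] == pytest.approx(0.3 / (0.01 / 100 + 0.01 / 100))
        assert vd_printed[1] == 0.0
        vd_welch = pairwise_metric(sa, sb, n_total=100, variant="welch")
        assert vd_welch[0] == pytest.approx(0.3 / math.sqrt(0.01 / 3 + 0.01 / 3))
        assert vd_welch[1] == 0.0

    def test_equal_means_give_zero_regardless_of_variance(self):
        sa = _stats("a", 3, [0.5], [0.2])
        sb = _stats("b", 3, [0.5], [0.9])
        for variant in ("as_printed", "welch"):
            assert pairwise_metric(sa, sb, 10, variant)[0] == 0.0

    def test_zero_variance_distinct_means_is_infinite(self):
        sa = _stats("a", 3, [0.1], [0.0])
        sb = _stats("b", 3, [0.9], [0.0])
        for variant in ("as_printed", "welch"):
            assert np.isinf(pairwise_metric(sa, sb, 10, variant)[0])

    def test_symmetry(self, rng):
        mean_a, mean_b = rng.random(6), rng.random(6)
        var_a, var_b = rng.random(6), rng.random(6)
        sa, sb = _stats("a", 4, mean_a, var_a), _stats("b", 7, mean_b, var_b)
        for variant in ("as_printed", "welch"):
            assert np.array_equal(
                pairwise_metric(sa, sb, 30, variant), pairwise_metric(sb, sa, 30, variant)
            )

    def test_welch_scale_invariance(self, rng):
        """Scaling one feature's column by c > 0 in all classes leaves the
        Welch statistic unchanged (numerator and denominator scale alike)."""
        m = rng.random((10, 4))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        base = fit_selection(m, labels, k=4, variant="welch").final_metric
        scaled = m.copy()
        scaled[:, 2] *= 7.5
        after = fit_selection(scaled, labels, k=4, variant="welch").final_metric
        assert np.allclose(base, after, rtol=1e-10)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ShapeError):
            pairwise_metric(_stats("a", 3, [0.1, 0.2], [0, 0]), _stats("b", 3, [0.1], [0]), 10)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ParameterError):
            pairwise_metric(_stats("a", 3, [0.1], [0]), _stats("b", 3, [0.1], [0]), 10, "typo")


class TestFinalMetricAndSelection:
    def test_single_pair_passthrough(self):
        row = np.array([[3.0, 1.0, 2.0]])
        assert np.array_equal(final_metric(row), row[0])

    def test_min_over_pairs_matches_loop(self, rng):
        m = rng.random((3, 50))
        vd = final_metric(m)
        for j in range(50):
            assert vd[j] == min(m[i, j] for i in range(3))

    def test_infinities_participate_in_min(self):
        m = np.array([[np.inf, np.inf], [np.inf, 2.0]])
        assert np.array_equal(final_metric(m), [np.inf, 2.0])

    def test_empty_matrix_errors(self):
        with pytest.raises(ShapeError):
            final_metric(np.empty((0, 5)))

    def test_topk_ordering(self):
        res = select_features((("a", "b"),), np.array([[3.0, 1.0, 2.0]]), k=2)
        assert res.selected.tolist() == [0, 2]
        assert res.ranking.tolist() == [0, 2, 1]

    def test_ties_broken_by_ascending_index(self):
        res = select_features((("a", "b"),), np.ones((1, 3)), k=3)
        assert res.selected.tolist() == [0, 1, 2]

    def test_k_equals_n_total(self):
        vd = np.array([[0.5, 2.0, 1.0]])
        res = select_features((("a", "b"),), vd, k=3)
        assert res.selected.tolist() == [1, 2, 0]

    def test_k_out_of_range(self):
        with pytest.raises(ParameterError):
            select_features((("a", "b"),), np.ones((1, 3)), k=4)

    def test_min_metric_threshold_mode(self):
        res = select_features((("a", "b"),), np.array([[3.0, 1.0, 2.0]]), k=3, min_metric=1.5)
        assert res.selected.tolist() == [0, 2]

    def test_infinite_features_outrank_finite(self):
        vd = np.array([[1.0, np.inf, 5.0, np.inf]])
        res = select_features((("a", "b"),), vd, k=4)
        assert res.ranking.tolist() == [1, 3, 2, 0]


class TestFitSelectionProperties:
    def test_pair_count_is_c_choose_2(self, rng):
        m = rng.random((12, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = fit_selection(m, labels, k=5)
        assert res.pair_metric.shape == (3, 8)
        assert len(res.pair_labels) == 3

    def test_final_metric_bounded_by_every_pair(self, rng):
        m = rng.random((12, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        res = fit_selection(m, labels, k=5)
        assert (res.final_metric[None, :] <= res.pair_metric + 1e-15).all()

    def test_label_permutation_invariance(self, rng):
        m = rng.random((12, 8))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        base = fit_selection(m, labels, k=5)
        perm = np.concatenate([np.arange(8, 12), np.arange(0, 4), np.arange(4, 8)])
        res = fit_selection(m[perm], labels[perm], k=5)
        assert np.allclose(base.final_metric, res.final_metric)
        assert set(base.selected) == set(res.selected)

    def test_row_shuffle_within_class_invariance(self, rng):
        m = rng.random((10, 6))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        base = fit_selection(m, labels, k=3)
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(5)])
        res = fit_selection(m[perm], labels[perm], k=3)
        assert np.allclose(base.final_metric, res.final_metric)
        assert base.selected.tolist() == res.selected.tolist()

    @pytest.mark.parametrize("variant", ["as_printed", "welch"])
    def test_vectorized_matches_nested_loop_oracle(self, variant):
        """100 random small instances agree with the naive oracle to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_classes = int(rng.integers(2, 6))
            n_features = int(rng.integers(2, 31))
            labels, blocks = [], []
            for c in range(n_classes):
                n_rows = int(rng.integers(2, 11))
                labels += [f"c{c}"] * n_rows
                blocks.append(rng.random((n_rows, n_features)))
            m = np.vstack(blocks)
            res = fit_selection(m, np.array(labels), k=n_features, variant=variant)
            expected = _naive_selection(m, labels, variant, n_features)
            finite = np.isfinite(expected)
            assert np.array_equal(np.isfinite(res.final_metric), finite)
            assert np.allclose(
                res.final_metric[finite], np.asarray(expected)[finite], rtol=1e-10
            )

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateClassError):
            fit_selection(rng.random((4, 3)), np.array(["a"] * 4), k=2)


def test_rank_features_is_stable_descending(rng):
    metric = rng.integers(0, 5, size=20).astype(float)
    order = rank_features(metric)
    for i in range(len(order) - 1):
        a, b = order[i], order[i + 1]
        assert (metric[a], -a) >= (metric[b], -b)
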