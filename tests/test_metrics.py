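import numpy as np
import pytest
from sklearn.metrics import adjusted_mutual_info_score as sk_ami
from sklearn.metrics import silhouette_score as sk_silhouette

import oracles
from conftest import random_labeled_instance
from embedbench import (
    ami,
    ami_max_hdbscan,
    hd_baselines,
    interclass_corr,
    intraclass_corr,
    knn_accuracy,
    knn_graph,
    knn_recall,
    silhouette,
)
from embedbench.metrics import MetricError, expected_mutual_information


class TestKnnGraph:
    def test_collinear_hand_example(self):
        g = knn_graph(np.array([[0.0], [1.0], [3.0]]), k=1)
        assert g.indices.tolist() == [[1], [0], [1]]

    def test_complete_graph(self, rng):
        x = rng.normal(size=(8, 3))
        g = knn_graph(x, k=7)
        for i in range(8):
            assert sorted(g.indices[i]) == sorted(set(range(8)) - {i})

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(50, 5))
        g = knn_graph(x, k=10)
        assert np.array_equal(g.indices, oracles.brute_knn(x, 10))

    def test_tie_break_by_index(self):
        # four corners of a square: both non-adjacent corners tie; lower index wins
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g = knn_graph(x, k=2)
        assert g.indices[0].tolist() == [1, 2]  # both at distance 1, index order
        assert g.indices[3].tolist() == [1, 2]

    def test_k_out_of_range(self, rng):
        with pytest.raises(MetricError):
            knn_graph(rng.normal(size=(5, 2)), k=5)


class TestKnnAccuracy:
    def test_separated_identical_clusters(self):
        x = np.vstack([np.zeros((20, 2)), np.full((20, 2), 100.0)])
        labels = ["a"] * 20 + ["b"] * 20
        assert knn_accuracy(x, labels, k=10).value == 1.0

    def test_chance_level_random_labels(self, rng):
        n, c = 3000, 4
        x = rng.normal(size=(n, 2))
        labels = rng.integers(0, c, n)
        while np.bincount(labels).min() < 2:
            labels = rng.integers(0, c, n)
        values = [
            knn_accuracy(x, rng.permutation(labels), k=10).value for _ in range(5)
        ]
        # majority vote among k random labels is right ~1/C of the time
        assert abs(np.mean(values) - 1 / c) < 0.03

    def test_six_point_hand_instance(self):
        x = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        labels = ["A", "A", "B", "A", "B", "B"]
        expected = oracles.brute_knn_accuracy(x, labels, k=3)
        assert knn_accuracy(x, labels, k=3).value == pytest.approx(expected, abs=1e-12)

    def test_fraction_mode(self):
        x = np.array([[0.0], [0.1], [5.0], [5.1]])
        labels = ["a", "b", "a", "b"]
        mv = knn_accuracy(x, labels, k=1, mode="fraction")
        assert mv.value == 0.0  # each nearest neighbor has the other label


class TestKnnRecall:
    def test_identical_spaces(self, rng):
        x = rng.normal(size=(40, 4))
        assert knn_recall(x, x, k=5).value == 1.0

    def test_five_point_hand_instance(self):
        hd = np.array([[0, 0], [1, 0], [2, 0], [0, 3], [1, 3]], dtype=float)
        emb = np.array([[0, 0], [0, 1], [4, 0], [4, 1], [2, 2]], dtype=float)
        expected = oracles.brute_knn_recall(hd, emb, k=2)
        assert knn_recall(hd, emb, k=2).value == pytest.approx(expected, abs=1e-12)

    def test_row_mismatch(self, rng):
        with pytest.raises(MetricError):
            knn_recall(rng.normal(size=(10, 2)), rng.normal(size=(9, 2)), k=2)


class TestSilhouette:
    def test_symmetric_four_points(self):
        # two classes of coincident pairs separated by d_out: s = 1 - d_in/d_out
        d_in, d_out = 1.0, 50.0
        x = np.array([[0.0, 0], [d_in, 0], [d_out, 0], [d_out + d_in, 0]])
        labels = ["a", "a", "b", "b"]
        got = silhouette(x, labels).value
        expected = oracles.brute_silhouette(x, labels)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1 - d_in / d_out, abs=0.02)

    def test_random_labels_near_zero(self, rng):
        x = rng.normal(size=(600, 2))
        labels = rng.integers(0, 3, 600)
        assert abs(silhouette(x, labels).value) < 0.05

    def test_matches_sklearn(self, rng):
        x = rng.normal(size=(50, 3))
        labels = rng.integers(0, 4, 50)
        while np.bincount(labels).min() < 2:
            labels = rng.integers(0, 4, 50)
        assert silhouette(x, labels).value == pytest.approx(
            float(sk_silhouette(x, labels)), abs=1e-9
        )

    def test_single_class_error(self, rng):
        with pytest.raises(MetricError):
            silhouette(rng.normal(size=(5, 2)), ["a"] * 5)


class TestAMI:
    def test_identical_partitions(self):
        assert ami([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == pytest.approx(1.0, abs=1e-12)

    def test_constant_partition(self):
        assert ami([0, 0, 0, 0], [0, 1, 0, 1]) == 0.0

    def test_contingency_3113_exact(self):
        # labels realizing the contingency table [[3,1],[1,3]]
        a = [0, 0, 0, 0, 1, 1, 1, 1]
        b = [0, 0, 0, 1, 0, 1, 1, 1]
        assert ami(a, b) == pytest.approx(oracles.brute_ami(a, b), abs=1e-12)
        table = np.array([[3, 1], [1, 3]])
        assert expected_mutual_information(table) == pytest.approx(
            oracles.brute_emi(table), abs=1e-12
        )

    def test_symmetry(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert ami(a, b) == pytest.approx(ami(b, a), abs=1e-12)

    def test_matches_sklearn(self, rng):
        for _ in range(10):
            a = rng.integers(0, 5, 40)
            b = rng.integers(0, 4, 40)
            assert ami(a, b) == pytest.approx(float(sk_ami(a, b)), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(MetricError):
            ami([0, 1], [0, 1, 2])


class TestAmiMaxHdbscan:
    def test_singleton_grid_equals_single_ami(self, rng):
        x = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 8])
        labels = np.array([0] * 30 + [1] * 30)
        grid = [{"min_cluster_size": 10}]
        mv = ami_max_hdbscan(x, labels, grid=grid)
        assert mv.value == pytest.approx(mv.details["per_entry"][0]["ami"])

    def test_max_dominates_entries(self, rng):
        x = rng.normal(size=(80, 2))
        labels = rng.integers(0, 3, 80)
        mv = ami_max_hdbscan(x, labels, grid=[{"min_cluster_size": s} for s in (5, 15, 30)])
        assert all(mv.value >= e["ami"] for e in mv.details["per_entry"])

    def test_separated_blobs_recovered(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30]], dtype=float)
        x = np.vstack([rng.normal(size=(40, 2)) + c for c in centers])
        labels = np.repeat([0, 1, 2], 40)
        assert ami_max_hdbscan(x, labels).value >= 0.99


class TestCorrelations:
    def test_similarity_transform_perfect(self, rng):
        hd = rng.normal(size=(60, 2))
        labels = rng.integers(0, 4, 60)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        emb = 3.0 * hd @ rot.T + np.array([5.0, -2.0])
        assert interclass_corr(hd, emb, labels).value == pytest.approx(1.0, abs=1e-9)
        assert intraclass_corr(hd, emb, labels).value == pytest.approx(1.0, abs=1e-9)

    def test_reversed_triples(self):
        # 3 class centroids with HD distances (3,4,5) and 2D distances (5,4,3)
        hd = np.array([[0, 0], [3, 0], [0, 4]], dtype=float).repeat(2, axis=0)
        emb = np.array([[0, 0], [5, 0], [3.2, 2.4]], dtype=float).repeat(2, axis=0)
        labels = [0, 0, 1, 1, 2, 2]
        got = interclass_corr(hd, emb, labels).value
        assert got == pytest.approx(oracles.brute_interclass_corr(hd, emb, labels), abs=1e-9)
        assert got == pytest.approx(-1.0, abs=1e-6)

    def test_intraclass_reversed_variances(self):
        # 3 classes whose HD variances (1,2,3) appear exactly as (3,2,1) in 2D:
        # each class is a +-sqrt(v) pair around its centroid, so its variance is v
        def pair(center, v):
            return np.array([[center - np.sqrt(v), 0.0], [center + np.sqrt(v), 0.0]])

        hd = np.vstack([pair(10 * i, v) for i, v in enumerate((1, 2, 3))])
        emb = np.vstack([pair(10 * i, v) for i, v in enumerate((3, 2, 1))])
        labels = np.repeat([0, 1, 2], 2)
        assert intraclass_corr(hd, emb, labels).value == pytest.approx(-1.0, abs=1e-9)

    def test_matches_brute_force(self, rng):
        hd = rng.normal(size=(40, 5))
        emb = rng.normal(size=(40, 2))
        labels = rng.integers(0, 4, 40)
        while np.bincount(labels).min() < 2:
            labels = rng.integers(0, 4, 40)
        assert interclass_corr(hd, emb, labels).value == pytest.approx(
            oracles.brute_interclass_corr(hd, emb, labels), abs=1e-9
        )
        assert intraclass_corr(hd, emb, labels).value == pytest.approx(
            oracles.brute_intraclass_corr(hd, emb, labels), abs=1e-9
        )

    def test_too_few_classes(self, rng):
        x = rng.normal(size=(20, 3))
        with pytest.raises(MetricError):
            interclass_corr(x, x[:, :2], [0, 1] * 10)

    def test_spearman_flag(self, rng):
        hd = rng.normal(size=(40, 4))
        emb = rng.normal(size=(40, 2))
        labels = rng.integers(0, 4, 40)
        while np.bincount(labels).min() < 2:
            labels = rng.integers(0, 4, 40)
        mv = interclass_corr(hd, emb, labels, flavor="spearman")
        assert -1.0 <= mv.value <= 1.0 and mv.details["flavor"] == "spearman"


class TestProperties:
    def test_isometry_neutrality(self, rng):
        x, labels = random_labeled_instance(rng)
        emb = rng.normal(size=(len(x), 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        emb2 = emb @ rot.T + np.array([3.0, -7.0])
        for metric in (
            lambda e: knn_accuracy(e, labels, k=5).value,
            lambda e: knn_recall(x, e, k=5).value,
            lambda e: silhouette(e, labels).value,
            lambda e: interclass_corr(x, e, labels).value,
            lambda e: intraclass_corr(x, e, labels).value,
        ):
            assert metric(emb) == pytest.approx(metric(emb2), abs=1e-9)

    def test_oracle_equivalence_fuzzed(self):
        """All metrics match independent brute-force implementations."""
        rng = np.random.default_rng(1234)
        for _ in range(100):
            x, labels = random_labeled_instance(rng)
            emb = rng.normal(size=(len(x), 2))
            k = int(rng.integers(1, min(8, len(x) - 1)))
            g = knn_graph(x, k)
            assert np.array_equal(g.indices, oracles.brute_knn(x, k))
            assert knn_accuracy(x, labels, k=k).value == pytest.approx(
                oracles.brute_knn_accuracy(x, labels, k), abs=1e-9
            )
            assert knn_recall(x, emb, k=k).value == pytest.approx(
                oracles.brute_knn_recall(x, emb, k), abs=1e-9
            )
            assert silhouette(x, labels).value == pytest.approx(
                oracles.brute_silhouette(x, labels), abs=1e-9
            )
            assert interclass_corr(x, emb, labels).value == pytest.approx(
                oracles.brute_interclass_corr(x, emb, labels), abs=1e-9
            )
            assert intraclass_corr(x, emb, labels).value == pytest.approx(
                oracles.brute_intraclass_corr(x, emb, labels), abs=1e-9
            )
            other = rng.integers(0, 4, len(labels))
            assert ami(labels, other) == pytest.approx(
                oracles.brute_ami(labels, other), abs=1e-9
            )

    def test_range_enforcement_fuzzed(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            x, labels = random_labeled_instance(rng)
            emb = rng.normal(size=(len(x), 2))
            assert 0.0 <= knn_accuracy(x, labels, k=5).value <= 1.0
            assert 0.0 <= knn_recall(x, emb, k=5).value <= 1.0
            assert -1.0 <= silhouette(emb, labels).value <= 1.0
            v = interclass_corr(x, emb, labels).value
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12
            a = ami(labels, rng.integers(0, 3, len(labels)))
            assert a <= 1.0 + 1e-12

    def test_recall_chance_level(self, rng):
        n, k = 400, 10
        values = [
            knn_recall(rng.normal(size=(n, 8)), rng.normal(size=(n, 2)), k=k).value
            for _ in range(10)
        ]
        assert abs(np.mean(values) - k / (n - 1)) < 0.01


def test_hd_baselines_match_metrics(rng):
    x, labels = random_labeled_instance(rng)
    emb = x[:, :2]
    acc, sil = hd_baselines(emb, labels, k=5)
    assert acc == knn_accuracy(emb, labels, k=5).value
    assert sil == silhouette(emb, labels).value
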