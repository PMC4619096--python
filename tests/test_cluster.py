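"""Marker clustering, Davies-Bouldin, tract formation and marker selection."""

import itertools
import math
import warnings

import numpy as np
import pytest
from sklearn.metrics import davies_bouldin_score

from piecemeal import (
    KNNGenotypeImputer,
    MarkerClustering,
    PiecemealModel,
    build_model,
    davies_bouldin,
    kmeans_cluster,
    mask_to_panel,
    select_markers,
    sweep_k,
    target_clusters,
    train_piecemeal,
)
from piecemeal.cluster import filled_feature_values
from piecemeal.imputers import BaseImputerSpec

from _helpers import feature_matrix_from


def _random_features(rng, n):
    return feature_matrix_from(rng.uniform(0.5, 1.0, size=(n, n)))


class TestKMeans:
    def test_k1_and_kn_are_forced(self):
        rng = np.random.default_rng(0)
        fm = _random_features(rng, 8)
        one = kmeans_cluster(fm, 1, seed=0)
        assert set(one.cluster_of_marker.values()) == {0}
        full = kmeans_cluster(fm, 8, seed=0)
        assert sorted(full.cluster_of_marker.values()) == list(range(8))

    def test_recovers_planted_groups(self):
        rng = np.random.default_rng(1)
        n = 12
        values = np.empty((n, n))
        group = np.array([0] * 6 + [1] * 6)
        centers = {0: 0.2, 1: 0.9}
        for i in range(n):
            values[i] = centers[group[i]] + rng.uniform(-0.035, 0.035, size=n)
        fm = feature_matrix_from(np.clip(values, 0, 1))
        clustering = kmeans_cluster(fm, 2, seed=3, n_restarts=10)
        labels = np.array([clustering.cluster_of_marker[m] for m in fm.marker_ids])
        assert (labels[:6] == labels[0]).all()
        assert (labels[6:] == labels[6]).all()
        assert labels[0] != labels[6]

    def test_exhaustive_two_partition_minimum_wcss(self):
        rng = np.random.default_rng(4)
        fm = _random_features(rng, 6)
        X = filled_feature_values(fm)

        def wcss(labels):
            total = 0.0
            for lab in set(labels):
                pts = X[np.array(labels) == lab]
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        best = min(
            wcss(labels)
            for labels in itertools.product((0, 1), repeat=6)
            if len(set(labels)) == 2
        )
        clustering = kmeans_cluster(fm, 2, seed=0, n_restarts=10)
        labels = [clustering.cluster_of_marker[m] for m in fm.marker_ids]
        assert wcss(labels) == pytest.approx(best)

    def test_result_is_lloyd_stable(self):
        # one further assignment + update step cannot lower the WCSS
        rng = np.random.default_rng(5)
        fm = _random_features(rng, 15)
        clustering = kmeans_cluster(fm, 4, seed=2, n_restarts=10)
        X = filled_feature_values(fm)
        labels = np.array([clustering.cluster_of_marker[m] for m in fm.marker_ids])
        centroids = np.stack(
            [X[labels == c].mean(axis=0) if (labels == c).any() else np.zeros(X.shape[1])
             for c in range(4)]
        )
        d = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        before = d[np.arange(len(X)), labels].sum()
        reassigned = d.argmin(axis=1)
        after = d[np.arange(len(X)), reassigned].sum()
        assert after == pytest.approx(before, rel=1e-9)

    def test_invalid_k(self):
        fm = _random_features(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            kmeans_cluster(fm, 5)
        with pytest.raises(ValueError):
            kmeans_cluster(fm, 0)


class TestDaviesBouldin:
    def test_hand_example_1d(self):
        # effectively 1-D points {0, 2} and {10, 12} (identical columns just
        # scale every distance, and DB is scale-invariant):
        # s_i = 1, centroid distance 10, DB = (1/2) * 2 * (2/10) = 0.2
        fm = feature_matrix_from(
            np.repeat(np.array([[0.0], [2.0], [10.0], [12.0]]) / 12.0, 4, axis=1)
        )
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 1, 1])), 2)
        assert davies_bouldin(fm, clustering) == pytest.approx(0.2)

    def test_two_singletons_have_zero_index(self):
        fm = feature_matrix_from([[0.1, 0.1], [0.9, 0.9]])
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 1])), 2)
        assert davies_bouldin(fm, clustering) == 0.0

    def test_duplicating_points_leaves_index_unchanged(self):
        rng = np.random.default_rng(6)
        fm = _random_features(rng, 6)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 0, 1, 1, 1])), 2)
        base = davies_bouldin(fm, clustering)
        # duplicate every row; pad with constant columns (distance-neutral) to
        # keep the feature matrix square
        dup_values = np.hstack(
            [np.vstack([fm.values, fm.values]), np.full((12, 6), 0.5)]
        )
        dup = feature_matrix_from(dup_values, marker_ids=tuple(f"d{i}" for i in range(12)))
        dup_clustering = MarkerClustering(
            dict(zip(dup.marker_ids, [0, 0, 0, 1, 1, 1] * 2)), 2
        )
        assert davies_bouldin(dup, dup_clustering) == pytest.approx(base)

    def test_empty_cluster_warned_fewer_than_two_errors(self):
        fm = feature_matrix_from([[0.1, 0.2], [0.8, 0.9]])
        three = MarkerClustering(dict(zip(fm.marker_ids, [0, 2])), 3)
        with pytest.warns(UserWarning, match="empty"):
            davies_bouldin(fm, three)
        lone = MarkerClustering(dict(zip(fm.marker_ids, [0, 0])), 2)
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            davies_bouldin(fm, lone)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(8)
        fm = _random_features(rng, 10)
        clustering = kmeans_cluster(fm, 3, seed=1)
        labels = [clustering.cluster_of_marker[m] for m in fm.marker_ids]
        ours = davies_bouldin(fm, clustering)
        theirs = davies_bouldin_score(filled_feature_values(fm), labels)
        assert ours == pytest.approx(theirs)


class TestSweepK:
    def test_grid_size_and_determinism(self):
        rng = np.random.default_rng(9)
        fm = _random_features(rng, 30)
        grid = list(range(5, 31, 5))
        out1 = sweep_k(fm, grid, seed=0)
        out2 = sweep_k(fm, grid, seed=0)
        assert sorted(out1) == grid
        for k in grid:
            assert out1[k][0].cluster_of_marker == out2[k][0].cluster_of_marker
            assert out1[k][1] == pytest.approx(out2[k][1], nan_ok=True)

    def test_singleton_grid_matches_direct_call(self):
        rng = np.random.default_rng(10)
        fm = _random_features(rng, 12)
        out = sweep_k(fm, [4], seed=7)
        direct = kmeans_cluster(fm, 4, seed=7 + 4)
        assert out[4][0].cluster_of_marker == direct.cluster_of_marker


class TestTargetClusters:
    def test_bounds(self):
        fm = feature_matrix_from(np.ones((3, 3)), acc1_overall=0.9)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 1])), 2)
        targets = target_clusters(fm, clustering)
        assert targets[0] == targets[1] == frozenset(fm.marker_ids)
        low = feature_matrix_from(np.full((3, 3), 0.5), acc1_overall=0.9)
        assert all(t == frozenset() for t in target_clusters(low, clustering).values())

    def test_threshold_is_inclusive_mean(self):
        # C1 = {m00, m01}; a(m00, m02)=0.9, a(m01, m02)=0.7; mean 0.8 >= acc1 0.8
        values = np.array(
            [[0.5, 0.5, 0.9], [0.5, 0.5, 0.7], [0.5, 0.5, 0.5]]
        )
        fm = feature_matrix_from(values, acc1_overall=0.8)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 1])), 2)
        targets = target_clusters(fm, clustering)
        assert "m02" in targets[0]
        assert "m00" not in targets[0]

    def test_per_marker_mode_uses_own_baseline(self):
        values = np.array([[0.9, 0.6], [0.9, 0.6]])
        fm = feature_matrix_from(
            values, acc1_overall=0.95, acc1_per_marker=np.array([0.85, 0.55])
        )
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0])), 1)
        assert target_clusters(fm, clustering, "global_acc1")[0] == frozenset()
        assert target_clusters(fm, clustering, "per_marker")[0] == frozenset(
            fm.marker_ids
        )

    def test_empty_cluster_gets_empty_tract(self):
        fm = feature_matrix_from(np.ones((2, 2)), acc1_overall=0.5)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0])), 2)
        assert target_clusters(fm, clustering)[1] == frozenset()


class TestSelectMarkers:
    def test_argmax_and_none(self):
        values = np.array(
            [[0.5, 0.5, 0.9], [0.5, 0.5, 0.7], [0.5, 0.5, 0.5]]
        )
        fm = feature_matrix_from(values, acc1_overall=0.8)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 1])), 2)
        targets = {0: frozenset(["m02"]), 1: frozenset()}
        selected = select_markers(fm, clustering, targets)
        assert selected[0] == "m00"  # contribution 0.9 > 0.7
        assert selected[1] is None

    def test_tie_breaks_by_genomic_order(self):
        values = np.array([[0.5, 0.5, 0.8], [0.5, 0.5, 0.8], [0.5, 0.5, 0.5]])
        fm = feature_matrix_from(values)
        clustering = MarkerClustering(dict(zip(fm.marker_ids, [0, 0, 1])), 2)
        selected = select_markers(fm, clustering, {0: frozenset(["m02"]), 1: frozenset()})
        assert selected[0] == "m00"

    def test_invariant_to_member_insertion_order(self):
        rng = np.random.default_rng(11)
        fm = _random_features(rng, 8)
        labels = [0, 1, 0, 1, 0, 1, 0, 1]
        fwd = MarkerClustering(dict(zip(fm.marker_ids, labels)), 2)
        rev = MarkerClustering(
            dict(zip(reversed(fm.marker_ids), reversed(labels))), 2
        )
        targets = target_clusters(fm, fwd)
        assert select_markers(fm, fwd, targets) == select_markers(fm, rev, targets)


class TestModelAndTraining:
    def _spec(self):
        return BaseImputerSpec("knn", 7, 3)

    def test_model_invariants_enforced(self):
        fm = feature_matrix_from(np.ones((2, 2)), acc1_overall=0.5)
        from _helpers import make_panel

        panel = make_panel(4)
        clustering = MarkerClustering({"m02": 0, "m03": 0}, 1)
        with pytest.raises(ValueError, match="selected"):
            PiecemealModel(
                typed_panel=panel.restrict(["m00", "m01"]),
                untyped_ids=("m02", "m03"),
                clustering=clustering,
                target_clusters={0: frozenset()},
                selected_marker={0: "m02"},
                acc1_overall=0.5,
                threshold_mode="global_acc1",
                base_spec=self._spec(),
            )

    def test_model_save_load_round_trip(self, tmp_path, small_instance, knn_engine):
        model, _ = train_piecemeal(
            knn_engine,
            small_instance["reference"],
            small_instance["typed"],
            k_grid=(3,),
            n_folds=3,
            seed=1,
        )
        path = tmp_path / "model.json"
        model.save(path)
        back = PiecemealModel.load(path)
        assert back.untyped_ids == model.untyped_ids
        assert back.selected_marker == model.selected_marker
        assert back.target_clusters == model.target_clusters
        assert back.clustering.cluster_of_marker == model.clustering.cluster_of_marker
        assert back.typed_panel == model.typed_panel
        assert back.base_spec == model.base_spec
        assert back.acc1_overall == pytest.approx(model.acc1_overall)

    def test_covered_and_uncovered_partition_untyped(self, small_instance, knn_engine):
        model, _ = train_piecemeal(
            knn_engine,
            small_instance["reference"],
            small_instance["typed"],
            k_grid=(2, 4),
            n_folds=3,
            seed=2,
        )
        assert set(model.covered_ids) | set(model.uncovered_ids) == set(model.untyped_ids)
        assert not set(model.covered_ids) & set(model.uncovered_ids)

    def test_training_is_deterministic_per_seed(self, small_instance, knn_engine):
        kwargs = dict(k_grid=(2, 3), n_folds=3, seed=5)
        m1, a1 = train_piecemeal(
            knn_engine, small_instance["reference"], small_instance["typed"], **kwargs
        )
        m2, a2 = train_piecemeal(
            knn_engine, small_instance["reference"], small_instance["typed"], **kwargs
        )
        assert a1 == a2
        assert m1.selected_marker == m2.selected_marker
        assert m1.clustering.cluster_of_marker == m2.clustering.cluster_of_marker

    def test_perfect_recovery_cv_accuracy_is_one(self, perfect_instance):
        model, cv_acc = train_piecemeal(
            KNNGenotypeImputer(11, 1),
            perfect_instance["reference"].restrict_markers(
                perfect_instance["hierarchy"][1].ids
            ),
            perfect_instance["hierarchy"][0],
            k_grid=(2, 4),
            n_folds=5,
            seed=0,
        )
        assert cv_acc == 1.0
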