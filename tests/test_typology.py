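import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from typoclust.simulate import FEAR, NON_FEAR
from typoclust.typology import (TypologyClusterer, assign_labeled_volunteer,
                                dunn_index, enforce_min_size,
                                optimal_cluster_search, transform_feature_map)


def brute_force_dunn(points, labels):
    """Independent O(n^2) triple-loop oracle for the Dunn index."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    inter, diam = np.inf, 0.0
    for i in range(len(points)):
        for j in range(len(points)):
            if i == j:
                continue
            d = np.sqrt(np.sum((points[i] - points[j]) ** 2))
            if labels[i] == labels[j]:
                diam = max(diam, d)
            else:
                inter = min(inter, d)
    return np.inf if diam == 0 else inter / diam


# --- transform ------------------------------------------------------------

def _tiny_map(rows):
    return pd.DataFrame(rows, columns=["volunteer_id", "stimulus_id",
                                       "window_index", "label", "f"])


def test_transform_hand_check_single_feature():
    rows = [("v", "s0", 0, FEAR, 2.0), ("v", "s1", 0, FEAR, 4.0),
            ("v", "s2", 0, NON_FEAR, 1.0), ("v", "s3", 0, NON_FEAR, 1.0),
            ("v", "s4", 0, NON_FEAR, 1.0)]
    out = transform_feature_map(_tiny_map(rows), feature_names=["f"])
    np.testing.assert_allclose(out.loc["v"].to_numpy(),
                               [3.0, np.sqrt(2.0), 1.0, 0.0], atol=1e-9)


def test_transform_yields_228_columns(feature_map):
    dprime = transform_feature_map(feature_map)
    assert dprime.shape[1] == 228
    assert dprime.shape[0] == feature_map.volunteer_id.nunique()
    assert np.isfinite(dprime.to_numpy()).all()


def test_transform_missing_class_error_lists_volunteer():
    rows = [("v1", "s0", 0, FEAR, 1.0), ("v1", "s1", 0, FEAR, 2.0)]
    with pytest.raises(ValueError, match="v1.*non-fear"):
        transform_feature_map(_tiny_map(rows), feature_names=["f"])


def test_identical_windows_give_identical_profiles():
    rows = []
    for v in ("a", "b", "c"):
        rows += [(v, "s0", 0, FEAR, 2.0), (v, "s1", 0, FEAR, 4.0),
                 (v, "s2", 0, NON_FEAR, 1.0), (v, "s3", 0, NON_FEAR, 3.0)]
    out = transform_feature_map(_tiny_map(rows), feature_names=["f"])
    assert (out.nunique() == 1).all()


# --- Dunn index -----------------------------------------------------------

def test_dunn_two_line_clusters():
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    assert dunn_index(pts, [0, 0, 1, 1]) == pytest.approx(9.0)


def test_dunn_singletons_is_infinite():
    pts = np.array([[0.0], [5.0], [9.0]])
    assert dunn_index(pts, [0, 1, 2]) == np.inf


def test_dunn_overlapping_clusters_is_zero():
    pts = np.array([[0.0], [1.0], [0.0], [1.0]])
    assert dunn_index(pts, [0, 0, 1, 1]) == 0.0


def test_dunn_single_cluster_raises():
    with pytest.raises(ValueError):
        dunn_index(np.zeros((3, 1)), [0, 0, 0])


def test_dunn_matches_brute_force_oracle(rng):
    for _ in range(30):
        n = rng.integers(6, 30)
        pts = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, n)
        if len(np.unique(labels)) < 2:
            continue
        assert dunn_index(pts, labels) == pytest.approx(
            brute_force_dunn(pts, labels))


# --- optimal search -------------------------------------------------------

def test_search_recovers_two_separated_groups(rng):
    X = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(30, 1, (13, 4))])
    truth = np.array([0] * 12 + [1] * 13)
    labels, k, trace = optimal_cluster_search(X)
    assert k == 2
    assert adjusted_rand_score(truth, labels) == 1.0


def test_search_three_triplets_of_distant_points():
    X = np.repeat(np.array([[0.0], [100.0], [200.0]]), 3, axis=0)
    labels, k, _ = optimal_cluster_search(X, 2, 9)
    assert k == 3
    assert len(np.unique(labels)) == 3


def test_search_two_points_trivial():
    labels, k, _ = optimal_cluster_search(np.array([[0.0], [1.0]]))
    assert k == 2 and sorted(labels) == [0, 1]


def test_search_single_point_raises():
    with pytest.raises(ValueError):
        optimal_cluster_search(np.zeros((1, 2)))


# --- minimum-size merge ---------------------------------------------------

def test_merge_noop_when_all_clusters_large_enough():
    X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
    labels = np.array([0, 0, 0, 1, 1, 1])
    out, log = enforce_min_size(labels, X, 0.15)
    assert log == [] and (out == labels).all()


def test_merge_singleton_into_nearest_cluster():
    # 1-D layout: big cluster near 0, mid cluster near 10, singleton at 12
    X = np.array([[0.0], [0.2], [0.4], [0.6], [0.8], [1.0],
                  [10.0], [10.2], [10.4], [12.0]])
    labels = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 2])
    out, log = enforce_min_size(labels, X, 0.15)
    sizes = np.bincount(out)
    assert sorted(sizes.tolist()) == [4, 6]
    assert log == [(2, 1)]


def test_merge_reduces_k_only_when_violations_exist():
    X = np.vstack([np.zeros((6, 1)), np.full((3, 1), 5.0), np.full((1, 1), 9.0)])
    labels = np.array([0] * 6 + [1] * 3 + [2])
    out, log = enforce_min_size(labels, X, 0.15)
    assert out.max() + 1 < 3 and len(log) == 1


def test_merge_collapse_to_single_cluster_raises():
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    labels = np.array([0, 0, 0, 1])
    with pytest.raises(ValueError, match="single cluster"):
        enforce_min_size(labels, X, 0.4)


# --- estimator ------------------------------------------------------------

def test_clusterer_assignment_matches_brute_force(rng):
    X = rng.normal(size=(20, 5))
    model = TypologyClusterer(min_frac=0.05).fit(X)
    rows = rng.normal(size=(10, 5))
    scaled = (rows - model.scale_mean_) / model.scale_std_
    for row, srow in zip(rows, scaled):
        dists = [np.linalg.norm(srow - c) for c in model.centroids_]
        assert assign_labeled_volunteer(row, model) == int(np.argmin(dists))


def test_clusterer_centroid_row_maps_to_own_cluster(m1_result):
    model = m1_result.clusterer
    # a D' row equal to a member's profile goes back to its own cluster
    pred = model.predict(m1_result.dprime)
    assert (pred == model.labels_).all()


def test_assignment_tie_breaks_to_lowest_index():
    model = TypologyClusterer(min_frac=0.05, standardize=False)
    X = np.array([[0.0, 0.0], [0.0, 0.1], [4.0, 0.0], [4.0, 0.1],
                  [0.0, 4.0], [0.1, 4.0]])
    model.fit(X)
    mid = (model.centroids_[0] + model.centroids_[1]) / 2
    d0 = np.linalg.norm(mid - model.centroids_[0])
    d1 = np.linalg.norm(mid - model.centroids_[1])
    assert d0 == pytest.approx(d1)
    assert model.predict(mid[None, :])[0] == 0


def test_dimension_mismatch_raises(m1_result):
    with pytest.raises(ValueError, match="dimension"):
        m1_result.clusterer.predict(np.zeros((1, 3)))


def test_permutation_invariance_of_partition(rng):
    X = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(12, 1, (9, 3))])
    perm = rng.permutation(len(X))
    a = TypologyClusterer(min_frac=0.1).fit(X).labels_
    b = TypologyClusterer(min_frac=0.1).fit(X[perm]).labels_
    assert adjusted_rand_score(a[perm], b) == 1.0


def test_min_share_invariant_on_fitted_cohort(m1_result):
    sizes = np.bincount(m1_result.clusterer.labels_)
    n = len(m1_result.clusterer.labels_)
    assert sizes.min() >= np.ceil(0.15 * n)
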