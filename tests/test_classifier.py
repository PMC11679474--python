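import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

from typoclust.classifier import (CostSensitiveKNN, KnnConfig, SearchSpace,
                                  laso_split, select_features, tune)


def _balanced_cloud(rng, n_pos, n_neg, dim=2, spread=1.0):
    X = rng.normal(scale=spread, size=(n_pos + n_neg, dim))
    y = np.array([1] * n_pos + [0] * n_neg)
    return X, y


# --- cost-weighted vote ---------------------------------------------------

def test_even_split_with_unit_cost_gives_half():
    rng = np.random.default_rng(0)
    X, y = _balanced_cloud(rng, 30, 30)
    m = CostSensitiveKNN(n_neighbors=60, cost=1.0).fit(X, y)
    p = m.predict_proba(np.zeros((1, 2)))[0, 1]
    assert p == pytest.approx(0.5)


def test_cost_two_with_20_40_split_gives_half():
    rng = np.random.default_rng(1)
    X, y = _balanced_cloud(rng, 20, 40)
    m = CostSensitiveKNN(n_neighbors=60, cost=2.0).fit(X, y)
    p = m.predict_proba(np.zeros((1, 2)))[0, 1]
    assert p == pytest.approx((2 * 20) / (2 * 20 + 40))


def test_unit_cost_reduces_to_reference_knn(rng):
    for _ in range(10):
        X, y = _balanced_cloud(rng, 20, 25, dim=3)
        Xq = rng.normal(size=(15, 3))
        ours = CostSensitiveKNN(n_neighbors=7, cost=1.0).fit(X, y).predict(Xq)
        ref = KNeighborsClassifier(n_neighbors=7).fit(X, y).predict(Xq)
        np.testing.assert_array_equal(ours, ref)


def test_probability_monotone_in_cost(rng):
    X, y = _balanced_cloud(rng, 25, 25, dim=2)
    Xq = rng.normal(size=(10, 2))
    probs = [CostSensitiveKNN(n_neighbors=20, cost=c).fit(X, y)
             .predict_proba(Xq)[:, 1] for c in (0.5, 1.0, 1.7, 2.5)]
    for lo, hi in zip(probs, probs[1:]):
        assert np.all(hi >= lo - 1e-12)
        assert np.all((lo >= 0) & (lo <= 1))


def test_manhattan_metric_changes_neighborhoods(rng):
    X, y = _balanced_cloud(rng, 30, 30, dim=4)
    m = CostSensitiveKNN(n_neighbors=9, metric="manhattan").fit(X, y)
    assert m.predict(rng.normal(size=(5, 4))).shape == (5,)


def test_too_few_training_points_raise(rng):
    X, y = _balanced_cloud(rng, 5, 5)
    with pytest.raises(ValueError, match="n_neighbors"):
        CostSensitiveKNN(n_neighbors=20).fit(X, y)


# --- feature selection ----------------------------------------------------

def _one_informative(rng, n=120, p=10):
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, p))
    X[:, 0] = y * 4.0 + 0.1 * rng.normal(size=n)  # near-perfect separator
    return X, y


def test_mrmr_ranks_separating_feature_first(rng):
    X, y = _one_informative(rng, p=20)
    sel = select_features(X, y, "mrmr", n_select=5)
    assert sel[0] == 0


def test_sfs_keeps_informative_feature(rng):
    X, y = _one_informative(rng, n=100, p=3)
    sel = select_features(X, y, "sfs")
    assert 0 in sel


def test_mrmr_boruta_screens_noise(rng):
    X, y = _one_informative(rng, n=120, p=8)
    sel = select_features(X, y, "mrmr-boruta", n_select=4)
    assert sel[0] == 0


def test_unknown_method_and_single_class_raise(rng):
    X = rng.normal(size=(20, 3))
    with pytest.raises(ValueError, match="unknown"):
        select_features(X, np.repeat([0, 1], 10), "pca")
    with pytest.raises(ValueError, match="two classes"):
        select_features(X, np.zeros(20), "mrmr")


# --- Bayesian tuning ------------------------------------------------------

def _local_structure(rng, n=160):
    """Interleaved pockets where small neighborhoods win and the global
    majority is the negative class (so k=100 collapses to one label)."""
    centers = rng.uniform(-10, 10, size=(16, 2))
    X, y = [], []
    for i, c in enumerate(centers):
        pts = c + 0.3 * rng.normal(size=(n // 16, 2))
        X.append(pts)
        y.extend([i % 2] * (n // 16))
    y = np.array(y)
    # make negatives the clear global majority
    extra = rng.uniform(-10, 10, size=(60, 2))
    return np.vstack(X + [extra]), np.concatenate([y, np.zeros(60, int)])


def test_collapsed_search_space_returns_single_config(rng):
    X, y = _balanced_cloud(rng, 40, 40, dim=2)
    space = SearchSpace(cost=(1.0, 1.0), n_neighbors=(20, 20),
                        metrics=("euclidean",))
    cfg = tune(X, y, space, n_iter=6, seed=0)
    assert cfg.cost == 1.0 and cfg.n_neighbors == 20 and cfg.metric == "euclidean"


def test_tuner_prefers_local_neighborhoods(rng):
    X, y = _local_structure(rng)
    cfg = tune(X, y, n_iter=15, seed=0)
    # grid oracle over the discretized space
    from typoclust.classifier import _cv_f1
    grid = {k: _cv_f1(X, y, KnnConfig(n_neighbors=k), 0) for k in (20, 60, 100)}
    assert grid[20] > grid[100]
    assert cfg.n_neighbors < 60
    assert cfg.cv_f1_ >= grid[20] - 0.05


def test_tuner_stable_across_seeds(rng):
    X, y = _local_structure(rng)
    a = tune(X, y, n_iter=12, seed=1)
    b = tune(X, y, n_iter=12, seed=2)
    assert abs(a.cv_f1_ - b.cv_f1_) < 0.05


def test_stratification_error_when_class_too_small(rng):
    X = rng.normal(size=(30, 2))
    y = np.array([1] * 3 + [0] * 27)
    with pytest.raises(ValueError, match="stratification"):
        tune(X, y, n_iter=4, seed=0)


def test_config_validation_flags_out_of_range():
    errs = KnnConfig(cost=3.0, n_neighbors=10, metric="cosine").validate()
    assert len(errs) == 3
    assert KnnConfig().validate() == []


# --- LASO split -----------------------------------------------------------

def test_laso_14_stimuli_split_sizes():
    labels = {f"s{i}": ("fear" if i < 7 else "non-fear") for i in range(14)}
    train, test = laso_split(labels, seed=3)
    assert len(test) == 7 and len(train) == 7
    fear_test = sum(labels[s] == "fear" for s in test)
    assert fear_test in (3, 4)


def test_laso_deterministic_and_disjoint():
    labels = {f"s{i}": ("fear" if i % 2 else "non-fear") for i in range(10)}
    a = laso_split(labels, seed=9)
    b = laso_split(labels, seed=9)
    assert a == b
    assert set(a[0]).isdisjoint(a[1])
    assert set(a[0]) | set(a[1]) == set(labels)


def test_laso_single_stimulus_raises():
    with pytest.raises(ValueError, match="at least two"):
        laso_split({"s0": "fear"}, seed=0)
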