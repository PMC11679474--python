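"""Cost-sensitive KNN fear classifier, feature selection, Bayesian tuning and
the LASO (Leave hAlf Subject Out) split.

The classifier is an ordinary KNN vote with one twist: the positive (fear)
class votes are weighted by a misclassification *cost* hyperparameter, so the
fear probability among the n nearest training neighbors is

    p = cost * k_pos / (cost * k_pos + k_neg)

with label 1 when p >= 0.5.  Cost ranges over [0.5, 2.5], the neighbor count
over [20, 100], and the metric over {euclidean, manhattan}; a
Gaussian-process Bayesian optimizer with 5-fold cross-validation picks the
combination maximizing mean F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SequentialFeatureSelector
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import f1_score, mutual_info_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted
from scipy.stats import binomtest, norm

COST_RANGE = (0.5, 2.5)
NEIGHBOR_RANGE = (20, 100)
METRICS = ("euclidean", "manhattan")
SELECTORS = ("mrmr", "sfs", "mrmr-boruta")


@dataclass
class KnnConfig:
    """Hyperparameter set for the cost-sensitive KNN."""

    cost: float = 1.0
    n_neighbors: int = 20
    metric: str = "euclidean"
    feature_selector: str = "mrmr"
    cv_folds: int = 5
    tuning_iterations: int = 30

    def validate(self) -> list[str]:
        errors = []
        if not COST_RANGE[0] <= self.cost <= COST_RANGE[1]:
            errors.append(f"cost {self.cost} outside {COST_RANGE}")
        if not NEIGHBOR_RANGE[0] <= self.n_neighbors <= NEIGHBOR_RANGE[1]:
            errors.append(f"n_neighbors {self.n_neighbors} outside {NEIGHBOR_RANGE}")
        if self.metric not in METRICS:
            errors.append(f"metric {self.metric!r} not in {METRICS}")
        if self.feature_selector not in SELECTORS:
            errors.append(f"feature_selector {self.feature_selector!r} not in {SELECTORS}")
        if self.cv_folds != 5:
            errors.append("cv_folds must be 5")
        return errors


class CostSensitiveKNN(ClassifierMixin, BaseEstimator):
    """Binary KNN with a positive-class vote weight (misclassification cost).

    With ``cost=1`` this reduces exactly to an unweighted KNN majority vote.
    The fear probability is monotone non-decreasing in ``cost`` for a fixed
    neighborhood.
    """

    def __init__(self, n_neighbors: int = 20, cost: float = 1.0,
                 metric: str = "euclidean"):
        self.n_neighbors = n_neighbors
        self.cost = cost
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] < self.n_neighbors:
            raise ValueError(
                f"{X.shape[0]} training points but n_neighbors={self.n_neighbors}"
            )
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CostSensitiveKNN is strictly binary")
        if self.cost <= 0:
            raise ValueError("cost must be positive")
        self._y = (y == self.classes_[1]).astype(int)  # positive = greater class
        self._nn = NearestNeighbors(n_neighbors=self.n_neighbors,
                                    metric=self.metric).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_nn")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, idx = self._nn.kneighbors(X)
        k_pos = self._y[idx].sum(axis=1)
        k_neg = self.n_neighbors - k_pos
        p = self.cost * k_pos / (self.cost * k_pos + k_neg)
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _binned_mi(a: np.ndarray, b: np.ndarray, bins: int = 8) -> float:
    """Mutual information between two vectors after quantile binning."""

    def _discretize(v):
        v = np.asarray(v, dtype=float)
        if len(np.unique(v)) <= bins:
            return v
        edges = np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1])
        return np.searchsorted(np.unique(edges), v)

    return mutual_info_score(_discretize(a), _discretize(b))


def _mrmr(X: np.ndarray, y: np.ndarray, n_select: int) -> list[int]:
    """Greedy minimal-redundancy maximal-relevance, MI-difference scheme."""
    p = X.shape[1]
    relevance = np.array([_binned_mi(X[:, j], y) for j in range(p)])
    selected = [int(np.argmax(relevance))]
    redundancy = np.zeros(p)
    while len(selected) < min(n_select, p):
        last = selected[-1]
        for j in range(p):
            if j not in selected:
                redundancy[j] += _binned_mi(X[:, j], X[:, last])
        score = relevance - redundancy / len(selected)
        score[selected] = -np.inf
        selected.append(int(np.argmax(score)))
    return selected


def _boruta_screen(X: np.ndarray, y: np.ndarray, seed: int, n_iter: int = 15,
                   alpha: float = 0.05) -> list[int]:
    """Boruta-style screening: features whose random-forest importance beats
    the best shadow (permuted) feature significantly often are accepted."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    hits = np.zeros(p, dtype=int)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        rf = RandomForestClassifier(n_estimators=100, random_state=seed + it,
                                    n_jobs=1)
        rf.fit(np.hstack([X, shadow]), y)
        imp = rf.feature_importances_
        hits += imp[:p] > imp[p:].max()
    accepted = [
        j for j in range(p)
        if binomtest(int(hits[j]), n_iter, 0.5, alternative="greater").pvalue < alpha
    ]
    return accepted if accepted else list(range(p))


def select_features(X, y, method: str = "mrmr", n_select: int = 30,
                    seed: int = 0) -> list[int]:
    """Select a non-empty feature subset by mRMR, SFS or mRMR-Boruta.

    Returns column indices; deterministic for a given seed.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs at least two classes")
    if method == "mrmr":
        return _mrmr(X, y, n_select)
    if method == "sfs":
        n = len(y)
        k = int(np.clip((n * 4) // 10, 1, 20))
        est = CostSensitiveKNN(n_neighbors=k)
        cv = StratifiedKFold(5, shuffle=True, random_state=seed)
        sfs = SequentialFeatureSelector(
            est, n_features_to_select="auto", tol=1e-4,
            direction="forward", scoring="f1", cv=cv, n_jobs=1,
        )
        sfs.fit(X, y)
        return list(np.where(sfs.get_support())[0])
    if method == "mrmr-boruta":
        survivors = _boruta_screen(X, y, seed)
        ranked = _mrmr(X[:, survivors], y, n_select)
        return [survivors[j] for j in ranked]
    raise ValueError(f"unknown feature-selection method {method!r}")


# ---------------------------------------------------------------------------
# Bayesian hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    cost: tuple[float, float] = COST_RANGE
    n_neighbors: tuple[int, int] = NEIGHBOR_RANGE
    metrics: tuple[str, ...] = METRICS


def _cv_f1(X, y, cfg: KnnConfig, seed: int) -> float:
    counts = np.bincount((y == np.unique(y)[1]).astype(int))
    if counts.min() < cfg.cv_folds:
        raise ValueError(
            "stratification error: a class has fewer samples than cv folds"
        )
    cv = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=seed)
    k = min(cfg.n_neighbors, int(len(y) * (cfg.cv_folds - 1) / cfg.cv_folds))
    est = CostSensitiveKNN(n_neighbors=k, cost=cfg.cost, metric=cfg.metric)
    return float(np.mean(cross_val_score(est, X, y, cv=cv, scoring="f1")))


def tune(X, y, space: SearchSpace | None = None, n_iter: int = 30,
         seed: int = 0, cv_folds: int = 5) -> KnnConfig:
    """Gaussian-process Bayesian optimization of (cost, n_neighbors, metric)
    maximizing mean 5-fold cross-validated F1.

    A third of the budget seeds the surrogate with random configurations;
    the remainder follows expected improvement over the encoded space.
    Deterministic for a given seed.
    """
    space = space or SearchSpace()
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)

    def _sample(m):
        return np.column_stack([
            rng.uniform(0, 1, m),       # cost (normalized)
            rng.uniform(0, 1, m),       # n_neighbors (normalized)
            rng.integers(0, len(space.metrics), m),  # metric index
        ])

    def _decode(x) -> KnnConfig:
        lo_c, hi_c = space.cost
        lo_k, hi_k = space.n_neighbors
        return KnnConfig(
            cost=float(lo_c + x[0] * (hi_c - lo_c)),
            n_neighbors=int(round(lo_k + x[1] * (hi_k - lo_k))),
            metric=space.metrics[int(x[2]) % len(space.metrics)],
            cv_folds=cv_folds,
            tuning_iterations=n_iter,
        )

    n_init = max(4, n_iter // 3)
    X_obs, y_obs = [], []
    tried = _sample(min(n_init, n_iter))
    for x in tried:
        X_obs.append(x)
        y_obs.append(_cv_f1(X, y, _decode(x), seed))
    gp = GaussianProcessRegressor(kernel=Matern(nu=2.5), normalize_y=True,
                                  alpha=1e-4, random_state=seed)
    while len(y_obs) < n_iter:
        gp.fit(np.array(X_obs), np.array(y_obs))
        cand = _sample(256)
        mu, sd = gp.predict(cand, return_std=True)
        best = max(y_obs)
        sd = np.maximum(sd, 1e-9)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        x = cand[int(np.argmax(ei))]
        X_obs.append(x)
        y_obs.append(_cv_f1(X, y, _decode(x), seed))
    best_cfg = _decode(X_obs[int(np.argmax(y_obs))])
    best_cfg.cv_f1_ = float(np.max(y_obs))
    return best_cfg


# ---------------------------------------------------------------------------
# LASO split
# ---------------------------------------------------------------------------

def laso_split(stimulus_labels: dict, seed: int = 0) -> tuple[list, list]:
    """Leave-hAlf-Subject-Out split of one volunteer's stimuli.

    Half of the volunteer's stimuli (stratified by label) form the test side;
    windows of one stimulus never straddle the split because the split is at
    stimulus granularity.  Returns (train_stimuli, test_stimuli).
    """
    if len(stimulus_labels) < 2:
        raise ValueError("volunteer needs at least two stimuli for a LASO split")
    rng = np.random.default_rng(seed)
    by_class: dict = {}
    for stim, lab in stimulus_labels.items():
        by_class.setdefault(lab, []).append(stim)
    for lab, stims in by_class.items():
        if len(stims) < 2:
            raise ValueError(f"class {lab!r} has fewer than two stimuli")
    target = len(stimulus_labels) // 2
    test: list = []
    leftovers = []
    for lab in sorted(by_class):
        stims = sorted(by_class[lab])
        rng.shuffle(stims)
        base = len(stims) // 2
        test.extend(stims[:base])
        if len(stims) % 2:
            leftovers.append(stims[base])
    rng.shuffle(leftovers)
    test.extend(leftovers[: target - len(test)])
    train = [s for s in stimulus_labels if s not in set(test)]
    return sorted(train), sorted(test)


@dataclass
class FittedModel:
    """A trained scope model: selected features + tuned config + estimator."""

    scope: str
    feature_subset: list
    config: KnnConfig
    estimator: CostSensitiveKNN = field(repr=False)


def fit_scope_model(X, y, scope: str = "general", config: KnnConfig | None = None,
                    feature_subset=None, select_method: str | None = None,
                    seed: int = 0) -> FittedModel:
    """Fit one scope (TC or general) model: optional feature selection, then
    the cost-sensitive KNN with a neighbor count clipped to the data size."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if feature_subset is None and select_method is not None:
        feature_subset = select_features(X, y, select_method, seed=seed)
    if feature_subset is None:
        feature_subset = list(range(X.shape[1]))
    config = config or KnnConfig()
    k = int(min(config.n_neighbors, len(y)))
    est = CostSensitiveKNN(n_neighbors=k, cost=config.cost, metric=config.metric)
    est.fit(X[:, feature_subset], y)
    return FittedModel(scope, list(feature_subset), config, est)
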