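"""Metrics, the weighted cluster average, and the validation harness.

Three validation indices probe a fitted typology system:

* performance — each TC's model evaluated, LASO-style, on the test halves of
  its own assigned volunteers;
* robustness — each TC's model evaluated on volunteers of the *other* TCs
  (stable typologies should score clearly lower here);
* assignment agreement — the percentage of held-out volunteers that the
  labeled (M1) and unlabeled (M2) assignment routes place in the same TC.

Per-cluster metrics are combined into a single figure by weighting each
cluster's metric with its volunteer count:

    m_avg = sum_c n_c * m_c / sum_c n_c

Metrics are computed per window and averaged across volunteers within a
scope; accuracy and F1 are reported on the percent scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score

from .classifier import FittedModel, KnnConfig, fit_scope_model, laso_split
from .features import FEATURE_NAMES
from .simulate import FEAR


def compute_metrics(y_true, y_pred) -> tuple[float, float]:
    """(accuracy %, F1 % of the positive/fear class); zero-division F1 is 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("cannot score empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors differ in length")
    acc = accuracy_score(y_true, y_pred) * 100.0
    f1 = f1_score(y_true, y_pred, zero_division=0) * 100.0
    return float(acc), float(f1)


def weighted_average(metrics, sizes) -> float:
    """Volunteer-count-weighted cluster average: sum(n_c m_c) / sum(n_c)."""
    metrics = np.asarray(metrics, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if metrics.shape != sizes.shape:
        raise ValueError("metrics and sizes must have equal length")
    if np.any(sizes <= 0):
        raise ValueError("cluster sizes must be positive")
    return float(np.sum(metrics * sizes) / np.sum(sizes))


def assignment_agreement(labels_m1: dict, labels_m2: dict) -> float:
    """Percent of volunteers assigned to the same TC by both methodologies."""
    if set(labels_m1) != set(labels_m2):
        raise ValueError("M1 and M2 assignments cover different volunteer sets")
    if not labels_m1:
        raise ValueError("empty assignment maps")
    same = sum(labels_m1[v] == labels_m2[v] for v in labels_m1)
    return 100.0 * same / len(labels_m1)


# ---------------------------------------------------------------------------
# LASO evaluation of scope models
# ---------------------------------------------------------------------------

def _binary(labels) -> np.ndarray:
    return (np.asarray(labels) == FEAR).astype(int)


def _stim_labels(fm: pd.DataFrame, volunteer) -> dict:
    sub = fm[fm.volunteer_id == volunteer]
    return dict(sub.groupby("stimulus_id")["label"].first())


def evaluate_scope(feature_map: pd.DataFrame, volunteers, config: KnnConfig,
                   seed: int = 0, feature_subset=None,
                   test_volunteers=None) -> tuple[float, float, pd.DataFrame]:
    """LASO evaluation of one scope (a TC's volunteers or the full set).

    For every test volunteer, half of their stimuli (stratified by label)
    are held out; the model trains on all scope windows outside that half and
    is scored on the held-out windows.  Per-volunteer window metrics are
    averaged.  Returns (mean accuracy %, mean F1 %, per-window predictions).
    """
    volunteers = list(volunteers)
    test_volunteers = list(test_volunteers) if test_volunteers is not None else volunteers
    scope_fm = feature_map[feature_map.volunteer_id.isin(volunteers)]
    accs, f1s, pred_rows = [], [], []
    for i, vol in enumerate(test_volunteers):
        train_stims, test_stims = laso_split(_stim_labels(feature_map, vol),
                                             seed=seed + 7 * i)
        test_mask = (feature_map.volunteer_id == vol) & \
            feature_map.stimulus_id.isin(test_stims)
        train_mask = scope_fm.volunteer_id.ne(vol) | scope_fm.stimulus_id.isin(train_stims)
        train = scope_fm[train_mask]
        test = feature_map[test_mask]
        model = fit_scope_model(train[FEATURE_NAMES], _binary(train.label),
                                config=config, feature_subset=feature_subset,
                                seed=seed)
        Xt = test[FEATURE_NAMES].to_numpy(dtype=float)[:, model.feature_subset]
        proba = model.estimator.predict_proba(Xt)[:, 1]
        y_true = _binary(test.label)
        y_pred = (proba >= 0.5).astype(int)
        acc, f1 = compute_metrics(y_true, y_pred)
        accs.append(acc)
        f1s.append(f1)
        pred_rows.append(pd.DataFrame({
            "volunteer_id": vol,
            "stimulus_id": test.stimulus_id.to_numpy(),
            "window_index": test.window_index.to_numpy(),
            "y_true": y_true, "p": proba, "y_pred": y_pred,
        }))
    preds = pd.concat(pred_rows, ignore_index=True) if pred_rows else pd.DataFrame()
    return float(np.mean(accs)), float(np.mean(f1s)), preds


def robustness_test(feature_map: pd.DataFrame, cluster_volunteers,
                    other_volunteers, config: KnnConfig, seed: int = 0
                    ) -> tuple[float, float]:
    """Score a TC's model on out-of-cluster volunteers' LASO test halves."""
    other_volunteers = list(other_volunteers)
    if not other_volunteers:
        raise ValueError("robustness test needs out-of-cluster volunteers")
    cluster_fm = feature_map[feature_map.volunteer_id.isin(list(cluster_volunteers))]
    model = fit_scope_model(cluster_fm[FEATURE_NAMES], _binary(cluster_fm.label),
                            config=config, seed=seed)
    accs, f1s = [], []
    for i, vol in enumerate(other_volunteers):
        _, test_stims = laso_split(_stim_labels(feature_map, vol), seed=seed + 7 * i)
        test = feature_map[(feature_map.volunteer_id == vol)
                           & feature_map.stimulus_id.isin(test_stims)]
        Xt = test[FEATURE_NAMES].to_numpy(dtype=float)[:, model.feature_subset]
        y_pred = model.estimator.predict(Xt)
        acc, f1 = compute_metrics(_binary(test.label), y_pred)
        accs.append(acc)
        f1s.append(f1)
    return float(np.mean(accs)), float(np.mean(f1s))


def split_volunteers(volunteers, train_frac: float = 0.7, seed: int = 0,
                     strata=None) -> tuple[list, list]:
    """Random 70-30 volunteer partition, optionally stratified (e.g. by
    generator typology truth when available)."""
    volunteers = list(volunteers)
    rng = np.random.default_rng(seed)
    if strata is None:
        order = list(volunteers)
        rng.shuffle(order)
        n_train = max(2, int(round(train_frac * len(order))))
        return sorted(order[:n_train]), sorted(order[n_train:])
    groups: dict = {}
    for v, s in zip(volunteers, strata):
        groups.setdefault(s, []).append(v)
    train, test = [], []
    for s in sorted(groups):
        vs = sorted(groups[s])
        rng.shuffle(vs)
        n_train = max(1, int(round(train_frac * len(vs))))
        train.extend(vs[:n_train])
        test.extend(vs[n_train:])
    return sorted(train), sorted(test)
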