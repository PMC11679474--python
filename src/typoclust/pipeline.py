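"""End-to-end orchestration: simulate -> preprocess -> features -> cluster
-> enroll -> train -> fuse -> report.

`run_m1` runs the data-preparation and cluster-generation phases on one
cohort; `run_experiment` runs the full three-configuration evaluation
(per-TC models from the labeled M1 assignments, per-TC models from the
unlabeled M2 assignments, and the general baseline) and emits a tidy report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import KnnConfig
from .config import ExperimentConfig, validate_config
from .enrollment import InternalClusterEnroller
from .evaluation import (assignment_agreement, evaluate_scope, robustness_test,
                         split_volunteers, weighted_average)
from .features import FEATURE_NAMES, build_feature_map, zscore_normalize
from .preprocessing import preprocess_cohort
from .simulate import CohortSpec, generate_cohort
from .typology import TypologyClusterer, transform_feature_map


@dataclass
class M1Result:
    """Artifacts of the data-preparation + cluster-generation phases."""

    feature_map: pd.DataFrame          # volunteer-normalized window features
    dprime: pd.DataFrame               # volunteers x 228 profile matrix
    clusterer: TypologyClusterer
    train_volunteers: list
    test_volunteers: list
    assignments_m1: dict = field(default_factory=dict)
    enroller: InternalClusterEnroller | None = None
    assignments_m2: dict = field(default_factory=dict)


def cohort_spec_from_config(cfg: ExperimentConfig, seed: int) -> CohortSpec:
    return CohortSpec(
        n_volunteers=cfg.n_volunteers,
        n_typologies=cfg.n_typologies,
        stimuli_per_volunteer=cfg.stimuli_per_volunteer,
        fear_fraction=cfg.fear_fraction,
        stimulus_duration=cfg.stimulus_duration,
        sampling_rate=cfg.sampling_rate,
        seed=seed,
    )


def prepare_feature_map(cohort, cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    cfg = cfg or ExperimentConfig()
    clean = preprocess_cohort(cohort, cfg.filter)
    return zscore_normalize(build_feature_map(clean, cfg.window))


def run_m1(cohort, cfg: ExperimentConfig | None = None, seed: int = 0,
           with_m2: bool = True, holdout: bool = True) -> M1Result:
    """Cluster a labeled cohort (M1), optionally building the M2 enrollment
    route and assigning the held-out 30% of volunteers via both."""
    cfg = cfg or ExperimentConfig()
    fm = prepare_feature_map(cohort, cfg)
    volunteers = sorted(fm.volunteer_id.unique())
    if holdout and len(volunteers) >= 7:
        truth = {r.volunteer_id: r.typology_truth for r in cohort}
        strata = [truth.get(v) for v in volunteers]
        strata = strata if all(s is not None for s in strata) else None
        train_vols, test_vols = split_volunteers(volunteers, cfg.train_frac,
                                                 seed=seed, strata=strata)
    else:
        train_vols, test_vols = volunteers, []

    dprime = transform_feature_map(fm)
    clusterer = TypologyClusterer(cfg.k_min, cfg.k_max, cfg.min_cluster_frac)
    clusterer.fit(dprime.loc[train_vols])
    assignments = {v: int(k) for v, k in zip(train_vols, clusterer.labels_)}
    if test_vols:
        assignments.update(
            {v: int(k) for v, k in
             zip(test_vols, clusterer.predict(dprime.loc[test_vols]))}
        )

    result = M1Result(fm, dprime, clusterer, train_vols, test_vols, assignments)
    if with_m2:
        train_fm = fm[fm.volunteer_id.isin(train_vols)]
        enroller = InternalClusterEnroller(cfg.ic_min, cfg.ic_max)
        enroller.fit(train_fm[FEATURE_NAMES],
                     train_fm.volunteer_id.map(assignments).to_numpy())
        result.enroller = enroller
        m2 = dict((v, assignments[v]) for v in train_vols)
        for v in test_vols:
            obs = fm.loc[fm.volunteer_id == v, FEATURE_NAMES].to_numpy(dtype=float)
            m2[v] = enroller.assign(obs)
        result.assignments_m2 = m2
    return result


def _scope_rows(fm, assignments, test_vols, cfg, seed, label):
    """Evaluate per-TC models (performance + robustness) for one assignment
    route; returns tidy rows."""
    knn = KnnConfig(feature_selector=cfg.feature_selector)
    rows = []
    clusters = sorted(set(assignments.values()))
    all_vols = sorted(assignments)
    for tc in clusters:
        members = [v for v in all_vols if assignments[v] == tc]
        others = [v for v in all_vols if assignments[v] != tc]
        if len(members) < 2:
            continue
        acc, f1, _ = evaluate_scope(fm, members, knn, seed=seed)
        rows.append((label, f"C{tc + 1}", "performance", len(members), acc, f1))
        if others:
            racc, rf1 = robustness_test(fm, members, others, knn, seed=seed)
            rows.append((label, f"C{tc + 1}", "robustness", len(members), racc, rf1))
    return rows


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None
                   ) -> pd.DataFrame:
    """Run the three-phase, three-configuration evaluation.

    Configurations: (1) per-TC models under the labeled M1 assignments,
    (2) per-TC models under the unlabeled M2 assignments, (3) the general
    baseline over all volunteers.  Repeats re-seed the cohort, the 70-30
    split and the LASO halves; the report carries mean and std over repeats.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    all_rows = []
    for rep in range(cfg.repeats):
        seed = cfg.seed + 1000 * rep
        cohort = generate_cohort(cohort_spec_from_config(cfg, seed))
        res = run_m1(cohort, cfg, seed=seed)
        fm = res.feature_map
        rows = _scope_rows(fm, res.assignments_m1, res.test_volunteers, cfg, seed, "M1")
        rows += _scope_rows(fm, res.assignments_m2, res.test_volunteers, cfg, seed, "M2")
        knn = KnnConfig(feature_selector=cfg.feature_selector)
        gacc, gf1, _ = evaluate_scope(fm, sorted(res.assignments_m1), knn, seed=seed)
        rows.append(("general", "all", "performance", len(res.assignments_m1), gacc, gf1))
        if res.test_volunteers:
            agree = assignment_agreement(
                {v: res.assignments_m1[v] for v in res.test_volunteers},
                {v: res.assignments_m2[v] for v in res.test_volunteers},
            )
            rows.append(("M1-vs-M2", "all", "agreement", len(res.test_volunteers),
                         agree, float("nan")))
        all_rows.extend([(rep,) + r for r in rows])

    report = pd.DataFrame(
        all_rows,
        columns=["repeat", "methodology", "scope", "index", "n_volunteers",
                 "accuracy", "f1"],
    )
    summary = (report.groupby(["methodology", "scope", "index"])
               .agg(n_volunteers=("n_volunteers", "mean"),
                    accuracy_mean=("accuracy", "mean"),
                    accuracy_std=("accuracy", "std"),
                    f1_mean=("f1", "mean"),
                    f1_std=("f1", "std"))
               .reset_index())
    # Eq.-3-style weighted aggregate of per-cluster performance
    for method in ("M1", "M2"):
        perf = summary[(summary.methodology == method) & (summary["index"] == "performance")]
        if len(perf):
            w_acc = weighted_average(perf.accuracy_mean, perf.n_volunteers)
            w_f1 = weighted_average(perf.f1_mean, perf.n_volunteers)
            summary.loc[len(summary)] = [method, "weighted", "performance",
                                         perf.n_volunteers.sum(), w_acc,
                                         float("nan"), w_f1, float("nan")]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "report.csv", index=False)
        summary.to_csv(out_dir / "summary.csv", index=False)
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "repeats": cfg.repeats,
            "config_sha256": hashlib.sha256(repr(cfg).encode()).hexdigest(),
        }
        with open(out_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh)
    return summary


def min_cluster_share(cohort_or_seed, cfg: ExperimentConfig | None = None) -> float:
    """Smallest typology-cluster share (fraction of volunteers) after the
    minimum-size merge, for one cohort or one generator seed."""
    cfg = cfg or ExperimentConfig()
    if isinstance(cohort_or_seed, int):
        cohort = generate_cohort(cohort_spec_from_config(cfg, cohort_or_seed))
    else:
        cohort = cohort_or_seed
    res = run_m1(cohort, cfg, with_m2=False, holdout=False)
    labels = res.clusterer.labels_
    sizes = np.bincount(labels)
    return float(sizes.min() / len(labels))
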