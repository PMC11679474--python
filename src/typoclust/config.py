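"""Experiment configuration: YAML round trip and aggregate validation.

The defaults pre-populate every protocol constant of the methodology:
20 s / 10 s windows, k in [2, 10] with a 15% minimum cluster share, internal
clusters in [4, 6], KNN cost in [0.5, 2.5] and neighbors in [20, 100],
5-fold tuning, 20 evaluation repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import yaml

from .classifier import COST_RANGE, METRICS, NEIGHBOR_RANGE, SELECTORS
from .fusion import STRATEGIES
from .preprocessing import FilterConfig, WindowConfig


@dataclass
class ExperimentConfig:
    # synthetic cohort
    n_volunteers: int = 16
    n_typologies: int = 3
    stimuli_per_volunteer: int = 14
    fear_fraction: float = 0.5
    stimulus_duration: float = 30.0
    sampling_rate: float = 100.0
    # preprocessing
    filter: FilterConfig = field(default_factory=FilterConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    # clustering
    k_min: int = 2
    k_max: int = 10
    min_cluster_frac: float = 0.15
    ic_min: int = 4
    ic_max: int = 6
    train_frac: float = 0.7
    # classifier search space
    cost_range: tuple[float, float] = COST_RANGE
    neighbor_range: tuple[int, int] = NEIGHBOR_RANGE
    metrics: tuple[str, ...] = METRICS
    feature_selector: str = "mrmr"
    tune_hyperparameters: bool = False
    tuning_iterations: int = 30
    # fusion
    fusion_strategy: str = "type1"
    fusion_alpha: dict = field(default_factory=dict)  # per-cluster contribution index
    # evaluation
    repeats: int = 20
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        raw = dict(raw)
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if "window" in raw and isinstance(raw["window"], dict):
            raw["window"] = WindowConfig(**raw["window"])
        if "seed" not in raw:
            warnings.warn("no seed given; defaulting to 0", stacklevel=2)
        for key in ("cost_range", "neighbor_range", "metrics"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Check every range/invariant; returns ALL violations, empty when ok."""
    errors: list[str] = []

    def _check(cond, msg):
        if not cond:
            errors.append(msg)

    _check(cfg.n_volunteers >= 4, "n_volunteers must be >= 4")
    _check(cfg.n_typologies >= 1, "n_typologies must be >= 1")
    _check(0 < cfg.fear_fraction < 1, "fear_fraction must lie in (0, 1)")
    _check(cfg.stimulus_duration > 0, "stimulus_duration must be > 0")
    _check(cfg.sampling_rate > 0, "sampling_rate must be > 0")
    try:
        cfg.filter.validate()
    except ValueError as exc:
        errors.append(str(exc))
    try:
        cfg.window.validate()
    except ValueError as exc:
        errors.append(str(exc))
    _check(2 <= cfg.k_min <= cfg.k_max <= 10, "cluster range must satisfy 2 <= k_min <= k_max <= 10")
    _check(0 < cfg.min_cluster_frac < 0.5, "min_cluster_frac must lie in (0, 0.5)")
    _check(4 <= cfg.ic_min <= cfg.ic_max <= 6, "IC range must satisfy 4 <= ic_min <= ic_max <= 6")
    _check(0 < cfg.train_frac < 1, "train_frac must lie in (0, 1)")
    _check(cfg.cost_range[0] >= COST_RANGE[0] and cfg.cost_range[1] <= COST_RANGE[1],
           f"cost range must lie within {COST_RANGE}")
    _check(cfg.neighbor_range[0] >= NEIGHBOR_RANGE[0]
           and cfg.neighbor_range[1] <= NEIGHBOR_RANGE[1],
           f"neighbor range must lie within {NEIGHBOR_RANGE}")
    _check(all(m in METRICS for m in cfg.metrics), f"metrics must be among {METRICS}")
    _check(cfg.feature_selector in SELECTORS, f"feature_selector must be one of {SELECTORS}")
    _check(cfg.fusion_strategy in STRATEGIES, f"fusion_strategy must be one of {STRATEGIES}")
    for k, a in cfg.fusion_alpha.items():
        _check(0 <= a <= 1, f"fusion alpha for cluster {k} must lie in [0, 1]")
    _check(cfg.repeats >= 1, "repeats must be >= 1")
    return errors
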