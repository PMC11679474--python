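"""Entropy-aware late fusion of personalized and general model outputs.

Both models emit a per-stimulus fear probability p (the mean of the
stimulus's window probabilities) with binary entropy

    h = -[p*log(p) + (1-p)*log(1-p)]       (natural log, p clipped)

as a confidence proxy.  Four decision-level strategies are provided:

* type1 — contribution index: fused p = (1-alpha)*p_personal + alpha*p_general;
  alpha=0 is the semi-personalized model alone, alpha=1 the general model.
* type2 — lowest entropy: the more confident model's label wins (tie: personal).
* type3 — inverse-entropy weighting: fused p = sum w_n p_n with
  w_n = (1/h_n) / sum(1/h_n), entropies floored at eps.
* type4 — logical OR of the two binary labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-12
STRATEGIES = ("type1", "type2", "type3", "type4")


def entropy(p) -> np.ndarray | float:
    """Binary entropy in nats with probabilities clipped to [eps, 1-eps]."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    q = np.clip(arr, EPS, 1.0 - EPS)
    h = -(q * np.log(q) + (1.0 - q) * np.log(1.0 - q))
    return float(h) if np.isscalar(p) else h


def _label(p):
    return (np.asarray(p, dtype=float) >= 0.5).astype(int)


@dataclass
class ModelOutput:
    """Per-stimulus fear probabilities with entropies and hard labels."""

    probabilities: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def entropies(self) -> np.ndarray:
        return entropy(self.probabilities)

    @property
    def labels(self) -> np.ndarray:
        return _label(self.probabilities)

    @classmethod
    def from_window_probs(cls, window_probs, stimulus_ids) -> "ModelOutput":
        """Aggregate window-level probabilities to per-stimulus means
        (stimuli in sorted id order)."""
        window_probs = np.asarray(window_probs, dtype=float)
        stimulus_ids = np.asarray(stimulus_ids)
        stims = sorted(set(stimulus_ids.tolist()))
        return cls(np.array([window_probs[stimulus_ids == s].mean() for s in stims]))


@dataclass(frozen=True)
class FusionConfig:
    strategy: str = "type1"
    alpha: float | None = None  # contribution index, required iff type1

    def validate(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown fusion strategy {self.strategy!r}")
        if self.strategy == "type1":
            if self.alpha is None or not 0.0 <= self.alpha <= 1.0:
                raise ValueError("type1 fusion requires alpha in [0, 1]")
        elif self.alpha is not None and self.strategy != "type1":
            raise ValueError("alpha is only meaningful for type1 fusion")


def fuse_type1(p_personal, p_general, alpha: float):
    """Contribution-index interpolation; returns (fused probabilities, labels)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    p = (1.0 - alpha) * np.asarray(p_personal, float) + alpha * np.asarray(p_general, float)
    return p, _label(p)


def fuse_type2(personal: ModelOutput, general: ModelOutput) -> np.ndarray:
    """Label of the lower-entropy (more confident) model; ties go personal."""
    hp, hg = personal.entropies, general.entropies
    return np.where(hp <= hg, personal.labels, general.labels)


def fuse_type3(personal: ModelOutput, general: ModelOutput):
    """Inverse-entropy weighted probability combination; returns (p, labels)."""
    inv_p = 1.0 / np.maximum(personal.entropies, EPS)
    inv_g = 1.0 / np.maximum(general.entropies, EPS)
    w_p = inv_p / (inv_p + inv_g)
    p = w_p * personal.probabilities + (1.0 - w_p) * general.probabilities
    return p, _label(p)


def fuse_type4(label_personal, label_general) -> np.ndarray:
    """Logical OR of the binary labels."""
    lp = np.asarray(label_personal)
    lg = np.asarray(label_general)
    for name, arr in (("personal", lp), ("general", lg)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary 0/1")
    return np.logical_or(lp, lg).astype(int)


def fuse(personal: ModelOutput, general: ModelOutput, config: FusionConfig) -> np.ndarray:
    """Dispatch to the configured strategy; returns fused binary labels."""
    config.validate()
    if config.strategy == "type1":
        return fuse_type1(personal.probabilities, general.probabilities, config.alpha)[1]
    if config.strategy == "type2":
        return fuse_type2(personal, general)
    if config.strategy == "type3":
        return fuse_type3(personal, general)[1]
    return fuse_type4(personal.labels, general.labels)
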