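"""Synthetic multi-volunteer biosignal cohorts with latent typologies.

Emulates a fear-elicitation study: each volunteer watches a fixed number of
audiovisual stimuli while blood volume pulse (BVP), galvanic skin response
(GSR) and skin temperature (SKT) are recorded at 100 Hz, and self-reports a
binary fear / non-fear label per stimulus.  Volunteers are drawn from latent
*typologies* that differ in how fear perturbs their physiology: heart-rate
acceleration, phasic electrodermal (SCR) arrival rate and amplitude, and skin
temperature drift.  The typology index is kept as ground truth so clustering
stages can be scored against it.

Signal models (deliberately minimal, carrying exactly the feature classes the
extractor measures):

* BVP — a two-harmonic pulse waveform driven by an instantaneous heart rate
  with slow sinusoidal variability, plus low-frequency drift and white noise.
  Fear shifts the base rate by the typology's ``hr_shift``.
* GSR — tonic level with a slow drift plus Poisson-arriving skin-conductance
  responses with exponential rise/decay; fear raises the arrival rate by
  ``scr_rate_shift`` (events/min) and the amplitude by ``scr_amp_shift`` (µS).
* SKT — baseline with a linear drift and band-limited slow noise; fear adds
  ``skt_slope_shift`` (°C/min) to the drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

FEAR = "fear"
NON_FEAR = "non-fear"
UNKNOWN = "unknown"
CHANNELS = ("bvp", "gsr", "skt")

# Fear-response palette used to derive default per-typology effects: tuples of
# (hr_shift bpm, scr_rate_shift events/min, scr_amp_shift uS, skt_slope_shift degC/min).
_EFFECT_PALETTE = [
    (22.0, 5.0, 0.70, -0.30),
    (4.0, 1.0, 0.12, -0.04),
    (-12.0, 3.0, 0.35, 0.20),
    (14.0, 0.5, 0.55, -0.14),
    (30.0, 7.0, 1.00, 0.08),
    (-4.0, 2.0, 0.22, -0.45),
]


@dataclass(frozen=True)
class TypologyEffect:
    """Fear-induced shifts that characterize one volunteer typology."""

    hr_shift: float = 15.0            # bpm added to heart rate under fear
    scr_rate_shift: float = 3.0       # SCR events/min added under fear
    scr_amp_shift: float = 0.5        # uS added to mean SCR amplitude under fear
    skt_slope_shift: float = -0.2     # degC/min added to SKT drift under fear


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic study cohort.

    Defaults mirror the study conditions this package emulates: 47 volunteers,
    14 stimuli each, three channels at 100 Hz, four latent typologies.
    """

    n_volunteers: int = 47
    n_typologies: int = 4
    stimuli_per_volunteer: int = 14
    fear_fraction: float = 0.5
    stimulus_duration: float = 60.0   # seconds
    sampling_rate: float = 100.0      # Hz
    typology_effects: tuple[TypologyEffect, ...] | None = None
    typology_weights: tuple[float, ...] | None = None
    noise_sd: dict = field(default_factory=lambda: {"bvp": 0.05, "gsr": 0.01, "skt": 0.01})
    labeled: bool = True
    seed: int = 0

    def effects(self) -> tuple[TypologyEffect, ...]:
        if self.typology_effects is not None:
            return tuple(self.typology_effects)
        pal = _EFFECT_PALETTE
        return tuple(TypologyEffect(*pal[g % len(pal)]) for g in range(self.n_typologies))

    def validate(self) -> None:
        if self.n_volunteers < 1:
            raise ValueError("n_volunteers must be >= 1")
        if self.n_typologies < 1:
            raise ValueError("n_typologies must be >= 1")
        if self.stimuli_per_volunteer < 1:
            raise ValueError("stimuli_per_volunteer must be >= 1")
        if not 0.0 < self.fear_fraction < 1.0:
            raise ValueError("fear_fraction must lie in (0, 1)")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus_duration must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.typology_effects is not None and len(self.typology_effects) != self.n_typologies:
            raise ValueError("typology_effects length must equal n_typologies")
        if self.typology_weights is not None:
            if len(self.typology_weights) != self.n_typologies:
                raise ValueError("typology_weights length must equal n_typologies")
            if any(w <= 0 for w in self.typology_weights):
                raise ValueError("typology_weights must be positive")
        for ch in CHANNELS:
            if ch not in self.noise_sd or self.noise_sd[ch] < 0:
                raise ValueError(f"noise_sd must map '{ch}' to a non-negative value")


@dataclass
class Segment:
    stimulus_id: str
    label: str
    bvp: np.ndarray
    gsr: np.ndarray
    skt: np.ndarray

    def __eq__(self, other):
        return (
            self.stimulus_id == other.stimulus_id
            and self.label == other.label
            and np.array_equal(self.bvp, other.bvp)
            and np.array_equal(self.gsr, other.gsr)
            and np.array_equal(self.skt, other.skt)
        )


@dataclass
class SignalRecording:
    """One volunteer's per-stimulus tri-channel recording."""

    volunteer_id: str
    segments: list[Segment]
    sampling_rate: float
    typology_truth: int | None = None

    def __eq__(self, other):
        return (
            self.volunteer_id == other.volunteer_id
            and self.sampling_rate == other.sampling_rate
            and self.typology_truth == other.typology_truth
            and self.segments == other.segments
        )


def _assign_typologies(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.typology_weights is None:
        # round-robin keeps every typology at >= floor(N/G) members
        truth = np.array([i % spec.n_typologies for i in range(spec.n_volunteers)])
    else:
        w = np.asarray(spec.typology_weights, dtype=float)
        counts = np.maximum(1, np.round(w / w.sum() * spec.n_volunteers).astype(int))
        while counts.sum() > spec.n_volunteers:
            counts[np.argmax(counts)] -= 1
        while counts.sum() < spec.n_volunteers:
            counts[np.argmax(w)] += 1
        truth = np.repeat(np.arange(spec.n_typologies), counts)
    rng.shuffle(truth)
    return truth


def _scr_kernel(rate: float) -> np.ndarray:
    t = np.arange(0.0, 10.0, 1.0 / rate)
    k = np.exp(-t / 3.0) - np.exp(-t / 0.7)
    return k / k.max()


def _bvp_segment(rng, n, rate, hr_bpm, noise_sd):
    t = np.arange(n) / rate
    f0 = hr_bpm / 60.0
    # slow rate variability (respiratory-ish and Mayer-wave-ish components)
    f_inst = f0 * (
        1.0
        + 0.03 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        + 0.02 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
    )
    phase = 2 * np.pi * np.cumsum(f_inst) / rate
    pulse = np.sin(phase) + 0.3 * np.sin(2 * phase + 1.0)
    drift = 0.5 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    return pulse + drift + rng.normal(0.0, noise_sd, n)


def _gsr_segment(rng, n, rate, tonic, drift_slope, scr_rate_per_min, scr_amp, noise_sd, kernel):
    t = np.arange(n) / rate
    sig = tonic + drift_slope * t
    n_events = rng.poisson(scr_rate_per_min * (n / rate) / 60.0)
    onsets = np.sort(rng.uniform(0, n / rate, n_events))
    amps = rng.lognormal(mean=math.log(max(scr_amp, 1e-3)), sigma=0.3, size=n_events)
    for onset, amp in zip(onsets, amps):
        i0 = int(onset * rate)
        seg = kernel[: n - i0]
        sig[i0 : i0 + len(seg)] += amp * seg
    return sig + rng.normal(0.0, noise_sd, n)


def _skt_segment(rng, n, rate, base, slope_per_min, noise_sd):
    t = np.arange(n) / rate
    slow = sum(
        a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        for a, f in ((0.05, 0.01), (0.03, 0.03), (0.02, 0.07))
    )
    return base + slope_per_min / 60.0 * t + slow + rng.normal(0.0, noise_sd, n)


def generate_cohort(spec: CohortSpec) -> list[SignalRecording]:
    """Generate a seeded cohort of :class:`SignalRecording`.

    Deterministic for a fixed spec (bit-identical output for repeated calls).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    effects = spec.effects()
    truth = _assign_typologies(spec, rng)
    n = int(round(spec.stimulus_duration * spec.sampling_rate))
    kernel = _scr_kernel(spec.sampling_rate)
    n_fear = int(round(spec.fear_fraction * spec.stimuli_per_volunteer))
    n_fear = min(max(n_fear, 1), spec.stimuli_per_volunteer - 1)

    cohort: list[SignalRecording] = []
    for v in range(spec.n_volunteers):
        eff = effects[truth[v]]
        hr_base = rng.normal(70.0, 5.0)
        tonic_base = rng.normal(8.0, 1.5)
        scr_rate_base = rng.uniform(1.0, 3.0)
        scr_amp_base = rng.uniform(0.3, 0.5)
        skt_base = rng.normal(33.0, 0.5)
        skt_slope_base = rng.normal(0.0, 0.02)  # degC/min

        labels = np.array([FEAR] * n_fear + [NON_FEAR] * (spec.stimuli_per_volunteer - n_fear))
        rng.shuffle(labels)

        segments = []
        for s, lab in enumerate(labels):
            fear = lab == FEAR
            bvp = _bvp_segment(
                rng, n, spec.sampling_rate,
                hr_base + (eff.hr_shift if fear else 0.0) + rng.normal(0.0, 1.0),
                spec.noise_sd["bvp"],
            )
            gsr = _gsr_segment(
                rng, n, spec.sampling_rate,
                tonic_base + rng.normal(0.0, 0.1),
                rng.normal(0.0, 0.005),
                scr_rate_base + (eff.scr_rate_shift if fear else 0.0),
                scr_amp_base + (eff.scr_amp_shift if fear else 0.0),
                spec.noise_sd["gsr"], kernel,
            )
            skt = _skt_segment(
                rng, n, spec.sampling_rate,
                skt_base + rng.normal(0.0, 0.05),
                skt_slope_base + (eff.skt_slope_shift if fear else 0.0),
                spec.noise_sd["skt"],
            )
            segments.append(
                Segment(f"stim{s:02d}", lab if spec.labeled else UNKNOWN, bvp, gsr, skt)
            )
        cohort.append(
            SignalRecording(f"vol{v:03d}", segments, spec.sampling_rate, int(truth[v]))
        )
    return cohort


# ---------------------------------------------------------------------------
# long-format CSV round trip
# ---------------------------------------------------------------------------

class CohortParseError(ValueError):
    """Raised when an on-disk cohort violates the long-format contract."""


def write_cohort(cohort: Sequence[SignalRecording], directory: str | Path) -> dict:
    """Write a cohort as one long-format signals CSV per volunteer plus a
    shared labels CSV, and return the YAML-serialized manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"n_recordings": len(cohort), "recordings": []}
    label_rows = []
    for rec in cohort:
        frames = []
        for seg in rec.segments:
            n = len(seg.bvp)
            t = np.arange(n) / rec.sampling_rate
            for ch in CHANNELS:
                frames.append(
                    pd.DataFrame(
                        {
                            "volunteer_id": rec.volunteer_id,
                            "stimulus_id": seg.stimulus_id,
                            "channel": ch,
                            "t_seconds": t,
                            "value": getattr(seg, ch),
                        }
                    )
                )
            label_rows.append((rec.volunteer_id, seg.stimulus_id, seg.label))
        fname = f"{rec.volunteer_id}.csv"
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                directory / fname, index=False, float_format="%.10g"
            )
        else:
            pd.DataFrame(
                columns=["volunteer_id", "stimulus_id", "channel", "t_seconds", "value"]
            ).to_csv(directory / fname, index=False)
        manifest["recordings"].append(
            {
                "volunteer_id": rec.volunteer_id,
                "file": fname,
                "sampling_rate": float(rec.sampling_rate),
                "typology_truth": rec.typology_truth,
            }
        )
    pd.DataFrame(label_rows, columns=["volunteer_id", "stimulus_id", "label"]).to_csv(
        directory / "labels.csv", index=False
    )
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest


def read_cohort(directory: str | Path) -> list[SignalRecording]:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    labels = pd.read_csv(directory / "labels.csv")
    label_of = {
        (r.volunteer_id, r.stimulus_id): r.label for r in labels.itertuples(index=False)
    }
    cohort = []
    for entry in manifest["recordings"]:
        df = pd.read_csv(directory / entry["file"])
        segments = []
        for stim, grp in df.groupby("stimulus_id", sort=False):
            channels = {}
            for ch in CHANNELS:
                channels[ch] = grp.loc[grp.channel == ch, "value"].to_numpy()
            lengths = {len(v) for v in channels.values()}
            if len(lengths) != 1:
                row = int(grp.index.min())
                raise CohortParseError(
                    f"{entry['file']}: mismatched channel lengths for stimulus "
                    f"{stim} (starting near row {row + 2}): "
                    + ", ".join(f"{ch}={len(v)}" for ch, v in channels.items())
                )
            segments.append(
                Segment(
                    str(stim),
                    label_of.get((entry["volunteer_id"], stim), UNKNOWN),
                    channels["bvp"], channels["gsr"], channels["skt"],
                )
            )
        cohort.append(
            SignalRecording(
                entry["volunteer_id"], segments, float(entry["sampling_rate"]),
                entry.get("typology_truth"),
            )
        )
    return cohort


def strip_labels(cohort: Sequence[SignalRecording]) -> list[SignalRecording]:
    """Copy a cohort with all stimulus labels replaced by ``unknown``
    (enrollment-time view of a new volunteer)."""
    out = []
    for rec in cohort:
        segs = [Segment(seg.stimulus_id, UNKNOWN, seg.bvp, seg.gsr, seg.skt) for seg in rec.segments]
        out.append(SignalRecording(rec.volunteer_id, segs, rec.sampling_rate, rec.typology_truth))
    return out
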