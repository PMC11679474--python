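"""Channel denoising and overlapping-window segmentation.

The BVP channel gets a direct-form low-pass FIR stage (half-amplitude point,
i.e. -6 dB, at 3.5 Hz) followed by drift removal: a forward-backward low-pass
Butterworth estimates the low-frequency drift, which is subtracted so the
cardiac pulse rides on a flat baseline.  GSR and SKT get a 2 Hz low-pass, a
1 s moving average and a 0.5 s moving median, in that order.  All stages are
length-preserving and constant-preserving; edges use reflection padding.
Signals at other rates are polyphase-resampled to the 100 Hz target first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter, uniform_filter1d

from .simulate import Segment, SignalRecording


@dataclass(frozen=True)
class FilterConfig:
    bvp_fir_cutoff: float = 3.5      # Hz, -6 dB point of the FIR stage
    bvp_fir_order: int = 101         # taps of the windowed-sinc design
    drift_cutoff: float = 0.2        # Hz, Butterworth drift estimator
    drift_order: int = 2
    gsr_skt_cutoff: float = 2.0      # Hz
    gsr_skt_order: int = 4
    moving_average_window: float = 1.0   # seconds
    moving_median_window: float = 0.5    # seconds
    target_rate: float = 100.0       # Hz

    def validate(self) -> None:
        nyq = self.target_rate / 2.0
        for name in ("bvp_fir_cutoff", "drift_cutoff", "gsr_skt_cutoff"):
            if not 0 < getattr(self, name) < nyq:
                raise ValueError(f"{name} must lie in (0, target_rate/2)")
        if self.moving_average_window <= 0 or self.moving_median_window <= 0:
            raise ValueError("moving windows must be > 0 seconds")


@dataclass(frozen=True)
class WindowConfig:
    length: float = 20.0    # seconds
    overlap: float = 10.0   # seconds

    def validate(self) -> None:
        if not 0 <= self.overlap < self.length:
            raise ValueError("require 0 <= overlap < length")


def _as_target_rate(x: np.ndarray, rate: float, cfg: FilterConfig) -> np.ndarray:
    if rate == cfg.target_rate:
        return x
    frac = Fraction(cfg.target_rate / rate).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def _check_length(x: np.ndarray, needed: int, what: str) -> None:
    if len(x) < needed:
        raise ValueError(f"series of length {len(x)} too short for {what} (needs >= {needed})")


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR with its group delay compensated, so the net
    stage is zero-phase and keeps the single-pass -6 dB design point."""
    half = (len(taps) - 1) // 2
    padded = np.pad(x, len(taps), mode="reflect")
    y = sps.lfilter(taps, 1.0, padded)
    return y[len(taps) + half : len(taps) + half + len(x)]


def estimate_drift(x: np.ndarray, rate: float, cfg: FilterConfig) -> np.ndarray:
    """Low-frequency drift via forward-backward Butterworth low-pass.

    Gustafsson initial-condition handling keeps the stage zero-phase to
    near machine precision even with the poles close to the unit circle.
    """
    b, a = sps.butter(cfg.drift_order, cfg.drift_cutoff, fs=rate)
    return sps.filtfilt(b, a, x, method="gust")


def filter_bvp(raw: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    cfg = cfg or FilterConfig()
    cfg.validate()
    x = _as_target_rate(np.asarray(raw, dtype=float), rate, cfg)
    _check_length(x, cfg.bvp_fir_order, "the BVP FIR stage")
    # firwin's cutoff is the half-amplitude (-6 dB) frequency
    taps = sps.firwin(cfg.bvp_fir_order, cfg.bvp_fir_cutoff, fs=cfg.target_rate)
    y = _zero_phase_fir(x, taps)
    return y - estimate_drift(y, cfg.target_rate, cfg)


def filter_tonic(raw: np.ndarray, rate: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Denoise a slow channel (GSR or SKT): low-pass, moving average, moving median."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    x = _as_target_rate(np.asarray(raw, dtype=float), rate, cfg)
    avg_n = max(1, int(round(cfg.moving_average_window * cfg.target_rate)))
    med_n = int(round(cfg.moving_median_window * cfg.target_rate))
    med_n += 1 - med_n % 2  # centered median needs odd length
    _check_length(x, max(avg_n, med_n, 3 * (cfg.gsr_skt_order + 1)), "the tonic filter chain")
    sos = sps.butter(cfg.gsr_skt_order, cfg.gsr_skt_cutoff, fs=cfg.target_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    y = uniform_filter1d(y, size=avg_n, mode="reflect")
    return median_filter(y, size=med_n, mode="reflect")


def segment(series: np.ndarray, rate: float, cfg: WindowConfig | None = None) -> list[np.ndarray]:
    """Cut a series into overlapping windows starting at t=0.

    Stride = length - overlap; trailing samples that do not fill a window are
    dropped.  A series shorter than one window yields an empty list and a
    warning rather than an error.
    """
    cfg = cfg or WindowConfig()
    cfg.validate()
    x = np.asarray(series)
    win = int(round(cfg.length * rate))
    stride = int(round((cfg.length - cfg.overlap) * rate))
    if len(x) < win:
        warnings.warn(
            f"series of {len(x)} samples is shorter than one {cfg.length} s window; "
            "returning no windows",
            stacklevel=2,
        )
        return []
    count = (len(x) - win) // stride + 1
    return [x[i * stride : i * stride + win] for i in range(count)]


def preprocess_recording(rec: SignalRecording, cfg: FilterConfig | None = None) -> SignalRecording:
    """Return a copy of ``rec`` with every segment's channels denoised."""
    cfg = cfg or FilterConfig()
    segs = [
        Segment(
            s.stimulus_id,
            s.label,
            filter_bvp(s.bvp, rec.sampling_rate, cfg),
            filter_tonic(s.gsr, rec.sampling_rate, cfg),
            filter_tonic(s.skt, rec.sampling_rate, cfg),
        )
        for s in rec.segments
    ]
    return SignalRecording(rec.volunteer_id, segs, cfg.target_rate, rec.typology_truth)


def preprocess_cohort(cohort, cfg: FilterConfig | None = None) -> list[SignalRecording]:
    cfg = cfg or FilterConfig()
    return [preprocess_recording(r, cfg) for r in cohort]
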