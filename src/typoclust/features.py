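"""57-feature window descriptor and per-volunteer Z-score normalization.

Each 20 s analysis window yields 57 features: 31 from BVP (4 time, 12
frequency, 15 non-linear), 20 from GSR (9 time, 3 frequency, 8 non-linear)
and 6 from SKT (4 time, 2 frequency).  The registry below is this package's
concrete realization of those counts — a compilation of the standard
heart-rate-variability, electrodermal and temperature descriptors of the
affective-computing literature — and is the single source of truth for
feature names and order.

BVP time/Poincaré features come from inter-beat intervals (IBIs) detected on
the pulse waveform; HRV band powers come from a 4 Hz-resampled IBI tachogram;
GSR is decomposed into a smooth tonic level and a phasic residual whose
skin-conductance responses (SCRs) are counted and measured.  Entropy and
fractal measures run on 4x-decimated window signals, which keeps them
tractable without changing their ordering across conditions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .simulate import SignalRecording
from .preprocessing import WindowConfig, segment

REGISTRY_VERSION = 1

_BVP_TIME = ["bvp_ibi_mean", "bvp_ibi_sdnn", "bvp_ibi_rmssd", "bvp_pibi50"]
_BVP_FREQ = [
    "bvp_hrv_p_vlf", "bvp_hrv_p_lf", "bvp_hrv_p_hf", "bvp_hrv_p_total",
    "bvp_hrv_lf_hf", "bvp_hrv_lf_nu", "bvp_hrv_hf_nu",
    "bvp_sig_p_total", "bvp_sig_peak_freq", "bvp_sig_centroid",
    "bvp_sig_spread", "bvp_sig_spec_entropy",
]
_BVP_NONLIN = [
    "bvp_poincare_sd1", "bvp_poincare_sd2", "bvp_poincare_ratio", "bvp_poincare_area",
    "bvp_sampen", "bvp_apen", "bvp_dfa_alpha1", "bvp_dfa_alpha2",
    "bvp_higuchi_fd", "bvp_petrosian_fd", "bvp_perm_entropy", "bvp_svd_entropy",
    "bvp_hjorth_mobility", "bvp_hjorth_complexity", "bvp_zcr",
]
_GSR_TIME = [
    "gsr_tonic_mean", "gsr_tonic_std", "gsr_tonic_slope", "gsr_range",
    "gsr_scr_count", "gsr_scr_amp_mean", "gsr_scr_amp_max",
    "gsr_scr_rise_mean", "gsr_scr_amp_sum",
]
_GSR_FREQ = ["gsr_p_low", "gsr_p_mid", "gsr_p_high"]
_GSR_NONLIN = [
    "gsr_sampen", "gsr_apen", "gsr_higuchi_fd", "gsr_petrosian_fd",
    "gsr_perm_entropy", "gsr_svd_entropy", "gsr_hjorth_mobility", "gsr_hjorth_complexity",
]
_SKT_TIME = ["skt_mean", "skt_std", "skt_slope", "skt_range"]
_SKT_FREQ = ["skt_p_low", "skt_p_mid"]

FEATURE_GROUPS: dict[tuple[str, str], list[str]] = {
    ("bvp", "time"): _BVP_TIME,
    ("bvp", "frequency"): _BVP_FREQ,
    ("bvp", "nonlinear"): _BVP_NONLIN,
    ("gsr", "time"): _GSR_TIME,
    ("gsr", "frequency"): _GSR_FREQ,
    ("gsr", "nonlinear"): _GSR_NONLIN,
    ("skt", "time"): _SKT_TIME,
    ("skt", "frequency"): _SKT_FREQ,
}
FEATURE_NAMES: list[str] = [n for names in FEATURE_GROUPS.values() for n in names]
N_FEATURES = len(FEATURE_NAMES)
ANNOTATION_COLUMNS = ["volunteer_id", "stimulus_id", "window_index", "label"]


def registry() -> pd.DataFrame:
    """Feature registry as a DataFrame (name, channel, domain), in order."""
    rows = [
        (name, ch, dom)
        for (ch, dom), names in FEATURE_GROUPS.items()
        for name in names
    ]
    return pd.DataFrame(rows, columns=["name", "channel", "domain"])


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def _safe(x, default=0.0):
    return float(x) if np.isfinite(x) else float(default)


def _slope(x, rate):
    t = np.arange(len(x)) / rate
    if np.ptp(x) == 0:
        return 0.0
    return _safe(linregress(t, x).slope)


def _bandpower(freqs, psd, lo, hi):
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        return 0.0
    return _safe(np.trapezoid(psd[mask], freqs[mask]))


def _welch(x, rate, nperseg=None):
    nperseg = min(len(x), nperseg or 4 * int(rate))
    return sps.welch(x, fs=rate, nperseg=nperseg)


def _find_peaks_bvp(x, rate):
    dist = max(1, int(0.3 * rate))
    amp = np.std(x)
    if amp == 0:
        return np.array([], dtype=int)
    peaks, _ = sps.find_peaks(x, distance=dist, prominence=0.5 * amp)
    return peaks


def _ibis(x, rate):
    peaks = _find_peaks_bvp(x, rate)
    if len(peaks) < 3:
        return np.array([])
    return np.diff(peaks) / rate  # seconds


def _sampen_apen(x, m=2, r_frac=0.2):
    """(Sample entropy, approximate entropy) at embedding m with r = r_frac*std."""
    x = np.asarray(x, float)
    n = len(x)
    if n < m + 2 or np.std(x) == 0:
        return 0.0, 0.0
    r = r_frac * np.std(x)

    def _counts(mm):
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        within = d <= r
        return within

    wm = _counts(m)
    wm1 = _counts(m + 1)
    # sample entropy: exclude self-matches
    b = wm[: len(wm1), : len(wm1)].sum() - len(wm1)
    a = wm1.sum() - len(wm1)
    sampen = -np.log(a / b) if a > 0 and b > 0 else 0.0
    # approximate entropy: include self-matches
    phi_m = np.mean(np.log(wm.mean(axis=1)))
    phi_m1 = np.mean(np.log(wm1.mean(axis=1)))
    return _safe(sampen), _safe(phi_m - phi_m1)


def _dfa(x, scales):
    x = np.asarray(x, float)
    if np.std(x) == 0:
        return 0.0
    y = np.cumsum(x - x.mean())
    flucts = []
    used = []
    for s in scales:
        if s >= len(x) // 2 or s < 4:
            continue
        n_seg = len(y) // s
        segs = y[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s)
        coef = np.polyfit(t, segs.T, 1)
        trend = np.outer(coef[0], t) + coef[1][:, None]
        flucts.append(np.sqrt(np.mean((segs - trend) ** 2)))
        used.append(s)
    if len(used) < 2:
        return 0.0
    return _safe(np.polyfit(np.log(used), np.log(flucts), 1)[0])


def _higuchi_fd(x, kmax=8):
    x = np.asarray(x, float)
    n = len(x)
    if np.std(x) == 0:
        return 0.0
    lks, ks = [], []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            lm.append(np.sum(np.abs(np.diff(x[idx]))) * (n - 1) / (len(idx) - 1) / k / k)
        if lm:
            lks.append(np.mean(lm))
            ks.append(k)
    if len(ks) < 2 or min(lks) <= 0:
        return 0.0
    return _safe(-np.polyfit(np.log(ks), np.log(lks), 1)[0])


def _petrosian_fd(x):
    d = np.diff(x)
    if np.all(d == 0):
        return 0.0
    nsc = np.sum(d[1:] * d[:-1] < 0)
    n = len(x)
    return _safe(np.log10(n) / (np.log10(n) + np.log10(n / (n + 0.4 * nsc))))


def _perm_entropy(x, order=3, delay=1):
    x = np.asarray(x, float)
    n = len(x) - (order - 1) * delay
    if n < 2:
        return 0.0
    emb = np.array([x[i : i + n : 1] for i in range(0, order * delay, delay)]).T
    ranks = np.argsort(np.argsort(emb, axis=1), axis=1)
    codes = ranks @ (order ** np.arange(order))
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return _safe(h / np.log(float(math.factorial(order))) if order > 1 else 0.0)


def _svd_entropy(x, order=10, delay=1):
    n = len(x) - (order - 1) * delay
    if n < order or np.std(x) == 0:
        return 0.0
    emb = np.lib.stride_tricks.sliding_window_view(np.asarray(x, float), order)[::delay]
    sv = np.linalg.svd(emb, compute_uv=False)
    sv = sv / sv.sum()
    sv = sv[sv > 0]
    return _safe(-np.sum(sv * np.log(sv)) / np.log(order))


def _hjorth(x):
    x = np.asarray(x, float)
    dx = np.diff(x)
    var0 = np.var(x)
    if var0 == 0:
        return 0.0, 0.0
    var1 = np.var(dx)
    mobility = np.sqrt(var1 / var0)
    ddx = np.diff(dx)
    var2 = np.var(ddx)
    complexity = np.sqrt(var2 / var1) / mobility if var1 > 0 and mobility > 0 else 0.0
    return _safe(mobility), _safe(complexity)


def _nonlinear_block(x, rate):
    """The 8 shared non-linear descriptors on a 4x-decimated signal."""
    xd = x[::4]
    sampen, apen = _sampen_apen(xd)
    pe = _perm_entropy(xd)
    se = _svd_entropy(xd)
    hm, hc = _hjorth(x)
    return xd, sampen, apen, pe, se, hm, hc


def _tonic_phasic(gsr, rate):
    """Split GSR into a smooth tonic level (2 s moving average twice) and a
    phasic residual."""
    from scipy.ndimage import uniform_filter1d

    n = max(1, int(2.0 * rate))
    tonic = uniform_filter1d(uniform_filter1d(gsr, n, mode="reflect"), n, mode="reflect")
    return tonic, gsr - tonic


def _scr_events(phasic, rate):
    """Detected SCR peaks in the phasic residual: (amplitudes, rise times)."""
    thresh = max(0.01, 2.0 * np.median(np.abs(phasic)))
    peaks, props = sps.find_peaks(phasic, prominence=thresh, distance=int(0.5 * rate))
    if len(peaks) == 0:
        return np.array([]), np.array([])
    amps = props["prominences"]
    rises = (peaks - props["left_bases"]) / rate
    return amps, rises


# ---------------------------------------------------------------------------
# per-channel feature blocks
# ---------------------------------------------------------------------------

def _bvp_features(x, rate):
    out = {}
    ibis = _ibis(x, rate)
    if len(ibis) >= 2:
        diffs = np.diff(ibis)
        out["bvp_ibi_mean"] = float(np.mean(ibis))
        out["bvp_ibi_sdnn"] = float(np.std(ibis, ddof=1))
        out["bvp_ibi_rmssd"] = float(np.sqrt(np.mean(diffs**2))) if len(diffs) else 0.0
        out["bvp_pibi50"] = float(np.mean(np.abs(diffs) > 0.05)) if len(diffs) else 0.0
    else:
        out.update({k: 0.0 for k in _BVP_TIME})

    # HRV bands from a 4 Hz tachogram
    if len(ibis) >= 4:
        beat_t = np.cumsum(ibis)
        t_res = np.arange(beat_t[0], beat_t[-1], 0.25)
        if len(t_res) >= 8:
            tach = np.interp(t_res, beat_t, ibis)
            f, p = _welch(tach - tach.mean(), 4.0, nperseg=len(t_res))
            vlf = _bandpower(f, p, 0.0033, 0.04)
            lf = _bandpower(f, p, 0.04, 0.15)
            hf = _bandpower(f, p, 0.15, 0.4)
        else:
            vlf = lf = hf = 0.0
    else:
        vlf = lf = hf = 0.0
    tot = vlf + lf + hf
    out["bvp_hrv_p_vlf"], out["bvp_hrv_p_lf"], out["bvp_hrv_p_hf"] = vlf, lf, hf
    out["bvp_hrv_p_total"] = tot
    out["bvp_hrv_lf_hf"] = lf / hf if hf > 0 else 0.0
    out["bvp_hrv_lf_nu"] = lf / (lf + hf) if lf + hf > 0 else 0.0
    out["bvp_hrv_hf_nu"] = hf / (lf + hf) if lf + hf > 0 else 0.0

    f, p = _welch(x - np.mean(x), rate)
    ptot = np.trapezoid(p, f)
    out["bvp_sig_p_total"] = _safe(ptot)
    out["bvp_sig_peak_freq"] = float(f[np.argmax(p)]) if ptot > 0 else 0.0
    if ptot > 0:
        w = p / p.sum()
        centroid = float(np.sum(f * w))
        out["bvp_sig_centroid"] = centroid
        out["bvp_sig_spread"] = float(np.sqrt(np.sum(w * (f - centroid) ** 2)))
        wp = w[w > 0]
        out["bvp_sig_spec_entropy"] = float(-np.sum(wp * np.log(wp)) / np.log(len(w)))
    else:
        out["bvp_sig_centroid"] = out["bvp_sig_spread"] = out["bvp_sig_spec_entropy"] = 0.0

    if len(ibis) >= 3:
        d = np.diff(ibis)
        sd1 = float(np.sqrt(np.var(d, ddof=1) / 2.0))
        sd2sq = 2 * np.var(ibis, ddof=1) - np.var(d, ddof=1) / 2.0
        sd2 = float(np.sqrt(max(sd2sq, 0.0)))
        out["bvp_poincare_sd1"] = sd1
        out["bvp_poincare_sd2"] = sd2
        out["bvp_poincare_ratio"] = sd1 / sd2 if sd2 > 0 else 0.0
        out["bvp_poincare_area"] = float(np.pi * sd1 * sd2)
    else:
        out.update({k: 0.0 for k in _BVP_NONLIN[:4]})

    xd, sampen, apen, pe, se, hm, hc = _nonlinear_block(x, rate)
    out["bvp_sampen"], out["bvp_apen"] = sampen, apen
    out["bvp_dfa_alpha1"] = _dfa(xd, [4, 6, 8, 12, 16])
    out["bvp_dfa_alpha2"] = _dfa(xd, [16, 24, 32, 48, 64])
    out["bvp_higuchi_fd"] = _higuchi_fd(xd)
    out["bvp_petrosian_fd"] = _petrosian_fd(x)
    out["bvp_perm_entropy"], out["bvp_svd_entropy"] = pe, se
    out["bvp_hjorth_mobility"], out["bvp_hjorth_complexity"] = hm, hc
    xc = x - np.mean(x)
    out["bvp_zcr"] = float(np.mean(xc[1:] * xc[:-1] < 0))
    return out


def _gsr_features(x, rate):
    out = {}
    tonic, phasic = _tonic_phasic(x, rate)
    out["gsr_tonic_mean"] = float(np.mean(x))  # mean skin-conductance level
    out["gsr_tonic_std"] = float(np.std(tonic, ddof=1)) if len(tonic) > 1 else 0.0
    out["gsr_tonic_slope"] = _slope(tonic, rate)
    out["gsr_range"] = float(np.ptp(x))
    amps, rises = _scr_events(phasic, rate)
    out["gsr_scr_count"] = float(len(amps))
    out["gsr_scr_amp_mean"] = float(np.mean(amps)) if len(amps) else 0.0
    out["gsr_scr_amp_max"] = float(np.max(amps)) if len(amps) else 0.0
    out["gsr_scr_rise_mean"] = float(np.mean(rises)) if len(rises) else 0.0
    out["gsr_scr_amp_sum"] = float(np.sum(amps))

    f, p = _welch(x - np.mean(x), rate)
    out["gsr_p_low"] = _bandpower(f, p, 0.01, 0.1)
    out["gsr_p_mid"] = _bandpower(f, p, 0.1, 0.5)
    out["gsr_p_high"] = _bandpower(f, p, 0.5, 1.0)

    xd, sampen, apen, pe, se, hm, hc = _nonlinear_block(x, rate)
    out["gsr_sampen"], out["gsr_apen"] = sampen, apen
    out["gsr_higuchi_fd"] = _higuchi_fd(xd)
    out["gsr_petrosian_fd"] = _petrosian_fd(x)
    out["gsr_perm_entropy"], out["gsr_svd_entropy"] = pe, se
    out["gsr_hjorth_mobility"], out["gsr_hjorth_complexity"] = hm, hc
    return out


def _skt_features(x, rate):
    out = {
        "skt_mean": float(np.mean(x)),
        "skt_std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "skt_slope": _slope(x, rate),
        "skt_range": float(np.ptp(x)),
    }
    f, p = _welch(x - np.mean(x), rate)
    out["skt_p_low"] = _bandpower(f, p, 0.003, 0.05)
    out["skt_p_mid"] = _bandpower(f, p, 0.05, 0.5)
    return out


def extract_features(window_bvp, window_gsr, window_skt, rate: float) -> np.ndarray:
    """Compute the 57-feature vector for one window triple, in registry order."""
    chans = {"bvp": np.asarray(window_bvp, float),
             "gsr": np.asarray(window_gsr, float),
             "skt": np.asarray(window_skt, float)}
    lengths = {len(v) for v in chans.values()}
    if len(lengths) != 1:
        raise ValueError(f"channel windows differ in length: "
                         + ", ".join(f"{k}={len(v)}" for k, v in chans.items()))
    if lengths.pop() < int(2 * rate):
        raise ValueError("window too short: need at least 2 s of samples")
    for name, v in chans.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in channel '{name}'")
    values = {}
    values.update(_bvp_features(chans["bvp"], rate))
    values.update(_gsr_features(chans["gsr"], rate))
    values.update(_skt_features(chans["skt"], rate))
    vec = np.array([values[n] for n in FEATURE_NAMES], dtype=float)
    assert vec.shape == (N_FEATURES,)
    return np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)


# ---------------------------------------------------------------------------
# feature map assembly and normalization
# ---------------------------------------------------------------------------

def build_feature_map(cohort: list[SignalRecording],
                      window_cfg: WindowConfig | None = None) -> pd.DataFrame:
    """Window every segment of a (preprocessed) cohort and extract features.

    Returns the feature map D: one row per window, annotation columns
    (volunteer_id, stimulus_id, window_index, label) followed by the 57
    feature columns in registry order.
    """
    window_cfg = window_cfg or WindowConfig()
    rows, annos = [], []
    for rec in cohort:
        for seg in rec.segments:
            wins = [segment(getattr(seg, ch), rec.sampling_rate, window_cfg)
                    for ch in ("bvp", "gsr", "skt")]
            for wi, (wb, wg, ws) in enumerate(zip(*wins)):
                rows.append(extract_features(wb, wg, ws, rec.sampling_rate))
                annos.append((rec.volunteer_id, seg.stimulus_id, wi, seg.label))
    anno = pd.DataFrame(annos, columns=ANNOTATION_COLUMNS)
    feat = pd.DataFrame(np.array(rows).reshape(-1, N_FEATURES), columns=FEATURE_NAMES)
    return pd.concat([anno, feat], axis=1)


def zscore_normalize(feature_map: pd.DataFrame) -> pd.DataFrame:
    """Individualized Z-score: per volunteer, each feature column is centered
    and scaled by its sample (n-1) standard deviation over that volunteer's
    windows.  Constant columns map to zero with a warning."""
    out = feature_map.copy()
    constant_hit = False
    for vol, idx in out.groupby("volunteer_id").groups.items():
        block = out.loc[idx, FEATURE_NAMES].to_numpy(dtype=float)
        if block.shape[0] < 2:
            raise ValueError(f"volunteer {vol} has a single window; cannot z-score")
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            constant_hit = True
        sd[const] = 1.0
        z = (block - mu) / sd
        z[:, const] = 0.0
        out.loc[idx, FEATURE_NAMES] = z
    if constant_hit:
        warnings.warn("constant feature column(s) mapped to zero during z-scoring",
                      stacklevel=2)
    return out
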