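"""Temporal and spectral tremor features.

From each of the four processed tri-axial signals (acceleration, angular
velocity, displacement, angle) a single composite magnitude series is
formed, and 19 features are computed from it: 3 temporal (mean peak-to-peak
amplitude, average regularity of the tremor rhythm, and its standard
deviation), 10 spectral, and 6 logarithms — 76 features per recording.

Spectral features come from one spectrum per signal, obtained by averaging
the Welch power spectral densities of the three axes at each frequency.
Three adaptive frequency bands are defined around the power-weighted mean
frequency MF: the tremor band [MF-3, MF+3] Hz (clamped to [0, 16]), the low
band below it and the high band above it, up to 16 Hz.  Absolute and
relative band powers make up six of the spectral features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import ProcessedSignals

__all__ = [
    "CompositeSignal",
    "PeakTrain",
    "Spectrum",
    "SIGNAL_NAMES",
    "FEATURE_ORDER",
    "FEATURE_NAMES",
    "composite",
    "detect_peaks",
    "mean_amplitude",
    "regularity",
    "averaged_spectrum",
    "spectral_features",
    "band_features",
    "extract",
]

F_MAX_HZ = 16.0
TREMOR_HALF_BAND_HZ = 3.0
LOG_EPSILON = 1e-12
MIN_PEAK_SEPARATION_S = 1.0 / (2.0 * F_MAX_HZ)  # half the period at 16 Hz
MIN_PROMINENCE_FRAC = 0.05  # of the composite's interquartile range
WELCH_WINDOW_SAMPLES = 512
WELCH_OVERLAP = 0.5

SIGNAL_NAMES = ("acc", "gyro", "disp", "angle")
FEATURE_ORDER = (
    "mean_amplitude",
    "avg_regularity",
    "sd_regularity",
    "peak_freq",
    "mean_freq",
    "peak_power",
    "mean_power",
    "P_low",
    "P_tr",
    "P_high",
    "Prl_low",
    "Prl_tr",
    "Prl_high",
    "log_mean_amplitude",
    "log_peak_power",
    "log_mean_power",
    "log_P_low",
    "log_P_tr",
    "log_P_high",
)
#: Canonical 76-column ordering of a full feature vector.
FEATURE_NAMES = tuple(f"{s}.{f}" for s in SIGNAL_NAMES for f in FEATURE_ORDER)


@dataclass
class CompositeSignal:
    """Nonnegative per-sample magnitude of a tri-axial signal."""

    values: np.ndarray
    sample_rate: float


@dataclass
class PeakTrain:
    """Alternating positive peaks (local maxima) and negative peaks (local
    minima) of a composite signal, with their times in seconds."""

    pos_times: np.ndarray
    pos_mags: np.ndarray
    neg_times: np.ndarray
    neg_mags: np.ndarray

    @property
    def degenerate(self) -> bool:
        return len(self.pos_times) < 2 or len(self.neg_times) < 2


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray


def composite(triaxial) -> np.ndarray:
    """Euclidean magnitude across the three axes at each sample."""
    triaxial = np.asarray(triaxial, dtype=float)
    if triaxial.shape[0] != 3:
        raise ValueError(f"expected a (3, M) array, got {triaxial.shape}")
    if not np.isfinite(triaxial).all():
        raise ValueError("signal contains non-finite samples")
    return np.sqrt((triaxial**2).sum(axis=0))


def _canonical_alternation(events: list[tuple[float, float, int]]):
    """Collapse runs of same-type extrema, keeping the extremal one.

    events: (time, magnitude, type) with type +1 for maxima, -1 for minima,
    sorted by time.  Returns the alternating subsequence.
    """
    out: list[tuple[float, float, int]] = []
    for t, m, kind in events:
        if out and out[-1][2] == kind:
            prev_t, prev_m, _ = out[-1]
            if (kind == +1 and m > prev_m) or (kind == -1 and m < prev_m):
                out[-1] = (t, m, kind)
        else:
            out.append((t, m, kind))
    return out


def detect_peaks(
    c: CompositeSignal,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
    min_prominence_frac: float = MIN_PROMINENCE_FRAC,
) -> PeakTrain:
    """Locate positive and negative peaks of the composite.

    A minimum peak separation of half the 16 Hz period forbids peaks faster
    than the analysis band, and a prominence floor (a fraction of the
    composite's interquartile range) ignores noise ripple.  Runs of
    same-type extrema are canonicalized so maxima and minima interleave.
    """
    x = np.asarray(c.values, dtype=float)
    if x.size < 3:
        raise ValueError("composite too short for peak detection")
    distance = max(1, int(round(min_separation_s * c.sample_rate)))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    prominence = min_prominence_frac * iqr if iqr > 0 else None
    pos_idx, _ = sps.find_peaks(x, distance=distance, prominence=prominence)
    neg_idx, _ = sps.find_peaks(-x, distance=distance, prominence=prominence)

    events = sorted(
        [(i / c.sample_rate, x[i], +1) for i in pos_idx]
        + [(i / c.sample_rate, x[i], -1) for i in neg_idx]
    )
    events = _canonical_alternation(events)
    pos = [(t, m) for t, m, k in events if k == +1]
    neg = [(t, m) for t, m, k in events if k == -1]
    return PeakTrain(
        pos_times=np.array([t for t, _ in pos]),
        pos_mags=np.array([m for _, m in pos]),
        neg_times=np.array([t for t, _ in neg]),
        neg_mags=np.array([m for _, m in neg]),
    )


def mean_amplitude(p: PeakTrain) -> float:
    """Mean peak-to-peak tremor amplitude.

    For the i-th positive peak pp_i flanked by negative peaks, two amplitude
    readings are formed — Amp1_i = |pp_i - np_i| against the preceding
    minimum and Amp2_i = |np_{i+1} - pp_i| against the following one — and
    the feature is the mean of (Amp1_i + Amp2_i)/2 over all flanked peaks.
    """
    if p.degenerate:
        warnings.warn("degenerate peak train: mean amplitude set to 0", stacklevel=2)
        return 0.0
    terms = []
    for tp, mp in zip(p.pos_times, p.pos_mags):
        before = np.flatnonzero(p.neg_times < tp)
        after = np.flatnonzero(p.neg_times > tp)
        if before.size == 0 or after.size == 0:
            continue
        amp1 = abs(mp - p.neg_mags[before[-1]])
        amp2 = abs(p.neg_mags[after[0]] - mp)
        terms.append(0.5 * (amp1 + amp2))
    if not terms:
        warnings.warn("no flanked positive peaks: mean amplitude set to 0", stacklevel=2)
        return 0.0
    return float(np.mean(terms))


def regularity(p: PeakTrain) -> tuple[float, float]:
    """Average and standard deviation of successive positive-peak intervals
    (seconds); the rhythm's period and its variability."""
    if len(p.pos_times) < 2:
        warnings.warn("fewer than 2 positive peaks: regularity set to 0", stacklevel=2)
        return 0.0, 0.0
    intervals = np.abs(np.diff(p.pos_times))
    return float(intervals.mean()), float(intervals.std())


def averaged_spectrum(
    triaxial,
    sample_rate: float,
    window_samples: int = WELCH_WINDOW_SAMPLES,
    overlap: float = WELCH_OVERLAP,
) -> Spectrum:
    """Welch PSD per axis, arithmetically averaged across the three axes.

    A Hann window of 512 samples (~4.1 s at 125 Hz, ~0.244 Hz resolution)
    with 50% overlap gives stable band powers on a 30-s segment.
    """
    triaxial = np.asarray(triaxial, dtype=float)
    if triaxial.shape[0] != 3:
        raise ValueError(f"expected a (3, M) array, got {triaxial.shape}")
    m = triaxial.shape[1]
    if m < 2 * window_samples:
        raise ValueError(
            f"signal too short for spectral estimation: {m} samples, "
            f"need >= {2 * window_samples} (2 windows)"
        )
    nperseg = window_samples
    freqs, pxx = sps.welch(
        triaxial,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=-1,
    )
    return Spectrum(freqs=freqs, power=pxx.mean(axis=0))


def spectral_features(sp: Spectrum, f_max: float = F_MAX_HZ) -> tuple[float, float, float, float]:
    """Peak frequency, mean frequency, peak power, mean power over (0, 16] Hz.

    MF is the power-weighted mean frequency sum(f_i P_i)/sum(P_i); peak
    power is the PSD at the peak frequency and mean power the PSD at the
    grid frequency nearest MF.
    """
    band = (sp.freqs > 0) & (sp.freqs <= f_max)
    f = sp.freqs[band]
    p = sp.power[band]
    total = p.sum()
    if f.size == 0 or total <= 0:
        warnings.warn("no spectral power in (0, 16] Hz: spectral features set to 0", stacklevel=2)
        return 0.0, 0.0, 0.0, 0.0
    i_peak = int(np.argmax(p))
    peak_freq = float(f[i_peak])
    peak_power = float(p[i_peak])
    mean_freq = float((f * p).sum() / total)
    mean_power = float(p[np.argmin(np.abs(f - mean_freq))])
    return peak_freq, mean_freq, peak_power, mean_power


def band_features(
    sp: Spectrum,
    mean_freq: float,
    f_max: float = F_MAX_HZ,
    half_band: float = TREMOR_HALF_BAND_HZ,
) -> tuple[float, float, float, float, float, float]:
    """Absolute and relative powers in the low / tremor / high bands.

    The tremor band is [MF-3, MF+3] Hz clamped to [0, 16]; band edges are
    assigned half-open/closed so every frequency bin belongs to exactly one
    band.  Relative powers are ratios to the total 0-16 Hz power.
    """
    if not 0 <= mean_freq <= f_max:
        raise ValueError(f"mean_freq must lie in [0, {f_max}], got {mean_freq}")
    f_tr1 = max(mean_freq - half_band, 0.0)
    f_tr2 = min(mean_freq + half_band, f_max)
    f = sp.freqs
    p = sp.power
    in_range = f <= f_max
    low = in_range & (f < f_tr1)
    tr = in_range & (f >= f_tr1) & (f <= f_tr2)
    high = in_range & (f > f_tr2)
    p_low = float(p[low].sum())
    p_tr = float(p[tr].sum())
    p_high = float(p[high].sum())
    total = p_low + p_tr + p_high
    if total <= 0:
        warnings.warn("zero total power: relative band powers set to 0", stacklevel=2)
        return p_low, p_tr, p_high, 0.0, 0.0, 0.0
    return p_low, p_tr, p_high, p_low / total, p_tr / total, p_high / total


def _log10_floored(v: float, eps: float = LOG_EPSILON) -> float:
    return float(np.log10(max(v, eps)))


def _signal_features(triaxial: np.ndarray, sample_rate: float, **cfg) -> dict[str, float]:
    comp = CompositeSignal(values=composite(triaxial), sample_rate=sample_rate)
    peaks = detect_peaks(
        comp,
        min_separation_s=cfg.get("min_separation_s", MIN_PEAK_SEPARATION_S),
        min_prominence_frac=cfg.get("min_prominence_frac", MIN_PROMINENCE_FRAC),
    )
    amp = mean_amplitude(peaks)
    avg_reg, sd_reg = regularity(peaks)
    sp = averaged_spectrum(
        triaxial,
        sample_rate,
        window_samples=cfg.get("window_samples", WELCH_WINDOW_SAMPLES),
        overlap=cfg.get("overlap", WELCH_OVERLAP),
    )
    pf, mf, pp, mp = spectral_features(sp)
    p_low, p_tr, p_high, prl_low, prl_tr, prl_high = band_features(sp, mf)
    eps = cfg.get("log_epsilon", LOG_EPSILON)
    return {
        "mean_amplitude": amp,
        "avg_regularity": avg_reg,
        "sd_regularity": sd_reg,
        "peak_freq": pf,
        "mean_freq": mf,
        "peak_power": pp,
        "mean_power": mp,
        "P_low": p_low,
        "P_tr": p_tr,
        "P_high": p_high,
        "Prl_low": prl_low,
        "Prl_tr": prl_tr,
        "Prl_high": prl_high,
        "log_mean_amplitude": _log10_floored(amp, eps),
        "log_peak_power": _log10_floored(pp, eps),
        "log_mean_power": _log10_floored(mp, eps),
        "log_P_low": _log10_floored(p_low, eps),
        "log_P_tr": _log10_floored(p_tr, eps),
        "log_P_high": _log10_floored(p_high, eps),
    }


def extract(signals: ProcessedSignals, **cfg):
    """Compute the canonical 76-feature vector of a processed recording.

    Returns a pandas Series indexed by ``signal.feature`` names in the
    canonical order (signals acc, gyro, disp, angle).
    """
    import pandas as pd

    values = {}
    for sig_name, triaxial in signals.as_dict().items():
        feats = _signal_features(triaxial, signals.sample_rate, **cfg)
        for feat_name in FEATURE_ORDER:
            values[f"{sig_name}.{feat_name}"] = feats[feat_name]
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def extract_from_recording(rec, **cfg):
    """Convenience: preprocess a raw recording and extract its 76 features."""
    from .preprocess import derive_all

    return extract(derive_all(rec), **cfg)


def feature_matrix(recordings, labels=None, **cfg):
    """Stack per-recording feature vectors into a DataFrame.

    If ``labels`` is given (or every recording carries one) a ``label``
    column is appended last.
    """
    import pandas as pd

    rows = [extract_from_recording(rec, **cfg) for rec in recordings]
    df = pd.DataFrame(rows).reset_index(drop=True)
    if labels is None and all(rec.label is not None for rec in recordings):
        labels = [rec.label for rec in recordings]
    if labels is not None:
        df["label"] = np.asarray(labels, dtype=int)
    return df
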