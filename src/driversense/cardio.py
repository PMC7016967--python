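"""PPG and GSR feature extraction.

PPG (blood-volume pulse, 51.2 Hz): moving-average smoothing, [0,1] scaling,
refractory peak detection (minimum inter-peak distance 0.5 s), heart rate as
peaks per minute, pNN50 heart-rate variability from RR intervals, and the
classic six time-domain statistics of the signal and its difference series.

GSR (electrodermal activity, 51.2 Hz): skin-conductance-response peak count
and mean absolute peak height (phasic SCR, measured peak minus preceding
trough so the tonic level cancels) plus the same six statistics (tonic SCL).

Both modalities can also be rendered as low-frequency STFT spectrogram
images (PPG 0-5 Hz, GSR 0-2 Hz — both signals live well below a few hertz)
for a CNN-style embedder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sp_signal


@dataclass
class PeakSet:
    """Detected peaks plus the successive RR (peak-to-peak) intervals."""

    peak_indices: np.ndarray
    peak_heights: np.ndarray
    rr_intervals_s: np.ndarray
    min_distance_s: float
    rate_hz: float

    def __post_init__(self):
        if len(self.peak_indices) > 1:
            gaps = np.diff(self.peak_indices)
            if np.any(gaps <= 0):
                raise ValueError("peak indices must be strictly increasing")
            if np.any(gaps < self.min_distance_s * self.rate_hz - 1e-9):
                raise ValueError("peaks violate the refractory distance")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)


@dataclass
class CardioFeatures:
    hr_bpm: float
    pnn50: float
    stat6: np.ndarray

    def __post_init__(self):
        if self.hr_bpm < 0:
            raise ValueError("heart rate cannot be negative")
        if not 0.0 <= self.pnn50 <= 1.0:
            raise ValueError("pNN50 is a fraction in [0, 1]")


def moving_average(x: np.ndarray, rate_hz: float,
                   window_s: float = 0.25) -> np.ndarray:
    """Centered moving mean; edges use a shrinking window (same length out)."""
    x = np.asarray(x, dtype=float).ravel()
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ValueError("window must span at least one sample")
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def minmax_scale(x: np.ndarray) -> np.ndarray:
    """Affine map of the signal onto [0, 1]; rejects constant input."""
    x = np.asarray(x, dtype=float).ravel()
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("constant signal has zero range; cannot scale to [0, 1]")
    return (x - lo) / (hi - lo)


def detect_peaks(x: np.ndarray, rate_hz: float, min_distance_s: float = 0.5,
                 threshold_frac: float = 0.5,
                 percentile_window_s: float = 10.0) -> PeakSet:
    """Refractory-filtered peak detection on a [0,1]-scaled signal.

    The height threshold adapts to slow amplitude drift: ``threshold_frac``
    times the rolling 90th percentile of the signal.  Of any two candidate
    peaks closer than ``min_distance_s`` only the taller survives.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("signal too short for peak detection")
    w = max(3, int(round(percentile_window_s * rate_hz)))
    w = min(w, len(x))
    thresh = threshold_frac * ndimage.percentile_filter(
        x, 90, size=w, mode="nearest")
    idx, props = sp_signal.find_peaks(
        x, height=thresh, distance=max(1, int(round(min_distance_s * rate_hz))))
    return PeakSet(
        peak_indices=idx,
        peak_heights=x[idx],
        rr_intervals_s=np.diff(idx) / rate_hz,
        min_distance_s=min_distance_s,
        rate_hz=rate_hz,
    )


def heart_rate(peaks: PeakSet | int, duration_s: float) -> float:
    """Heart rate in beats per minute: peak count x 60 / duration."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = peaks.n_peaks if isinstance(peaks, PeakSet) else int(peaks)
    return n * 60.0 / duration_s


def pnn50(rr_intervals_s: np.ndarray, threshold_s: float = 0.050) -> float:
    """Fraction of successive RR-interval differences exceeding 50 ms."""
    rr = np.asarray(rr_intervals_s, dtype=float).ravel()
    if len(rr) < 2:
        raise ValueError("pNN50 needs at least 2 RR intervals")
    diffs = np.abs(np.diff(rr))
    return float((diffs > threshold_s).sum() / len(diffs))


def stat6(x: np.ndarray) -> np.ndarray:
    """Six time-domain statistics of a signal and its difference series.

    (1) mean, (2) standard deviation, (3) mean |first difference|,
    (4) mean |first difference| of the standardized signal,
    (5) mean |second difference|, (6) same on the standardized signal.
    Features 4 and 6 equal 3/std and 5/std; a zero-variance signal gets 0
    there (with a warning) rather than a division blow-up.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("stat6 needs at least 3 samples")
    mu = x.mean()
    sd = x.std()
    d1 = np.abs(np.diff(x)).mean()
    d2 = np.abs(np.diff(x, n=2)).mean()
    if sd == 0:
        warnings.warn("zero-variance signal: standardized-difference "
                      "features set to 0", RuntimeWarning, stacklevel=2)
        d1n = d2n = 0.0
    else:
        d1n, d2n = d1 / sd, d2 / sd
    return np.array([mu, sd, d1, d1n, d2, d2n])


def gsr_peak_features(x: np.ndarray, rate_hz: float,
                      min_prominence: float = 0.05,
                      min_distance_s: float = 1.0) -> tuple[int, float]:
    """Count skin-conductance responses and their mean absolute height.

    SCR height is measured peak minus the preceding trough (onset), which
    separates the phasic response from the tonic skin-conductance level.
    Returns ``(0, 0.0)`` for a trace with no responses.
    """
    x = np.asarray(x, dtype=float).ravel()
    peaks, props = sp_signal.find_peaks(
        x, prominence=min_prominence,
        distance=max(1, int(round(min_distance_s * rate_hz))))
    if len(peaks) == 0:
        return 0, 0.0
    heights = []
    prev = 0
    for p in peaks:
        onset = prev + int(np.argmin(x[prev:p + 1]))
        heights.append(abs(x[p] - x[onset]))
        prev = p
    return len(peaks), float(np.mean(heights))


def ppg_features(x: np.ndarray, rate_hz: float) -> CardioFeatures:
    """Full PPG pipeline: smooth, scale, detect peaks, HR + pNN50 + stat6."""
    smooth = moving_average(x, rate_hz)
    scaled = minmax_scale(smooth)
    peaks = detect_peaks(scaled, rate_hz)
    hr = heart_rate(peaks, len(x) / rate_hz)
    if len(peaks.rr_intervals_s) >= 2:
        p50 = pnn50(peaks.rr_intervals_s)
    else:
        p50 = 0.0
    return CardioFeatures(hr_bpm=hr, pnn50=p50, stat6=stat6(scaled))


def gsr_features(x: np.ndarray, rate_hz: float) -> tuple[int, float, np.ndarray]:
    """Full GSR pipeline: smooth, SCR peak features, stat6 on the smoothed trace."""
    smooth = moving_average(x, rate_hz)
    n, h = gsr_peak_features(smooth, rate_hz)
    return n, h, stat6(smooth)


# ---------------------------------------------------------------------------
# Spectrogram images

@dataclass
class SpectrogramImage:
    """224x224x3 colormapped STFT magnitude, cropped to [0, f_max_hz]."""

    pixels: np.ndarray
    f_max_hz: float
    window_s: float
    overlap_frac: float
    power_db: np.ndarray          # underlying (freq x time) log-magnitude
    freqs_hz: np.ndarray

    def __post_init__(self):
        if self.pixels.shape != (224, 224, 3):
            raise ValueError(f"expected 224x224x3, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixels")
        if self.freqs_hz.max() > self.f_max_hz + 1e-9:
            raise ValueError("rows above f_max rendered")


def spectrogram_image(x: np.ndarray, rate_hz: float, f_max_hz: float,
                      window_s: float = 4.0, overlap_frac: float = 0.75,
                      colormap: str = "viridis") -> SpectrogramImage:
    """Low-frequency STFT magnitude rendered as a 224x224 RGB image.

    Hann-windowed STFT, rows cropped to [0, ``f_max_hz``], log10-scaled,
    min-max normalized, mapped through a perceptually-uniform colormap and
    bicubic-resized.  PPG uses ``f_max_hz=5``; GSR uses ``f_max_hz=2``.
    """
    import matplotlib
    from PIL import Image

    x = np.asarray(x, dtype=float).ravel()
    if f_max_hz > rate_hz / 2.0:
        raise ValueError(f"f_max={f_max_hz} Hz above Nyquist {rate_hz / 2} Hz")
    nper = int(round(window_s * rate_hz))
    if len(x) < 2 * nper - int(round(overlap_frac * nper)):
        raise ValueError(
            f"signal must span at least 2 STFT windows "
            f"({window_s} s at {overlap_frac:.0%} overlap)"
        )
    nov = int(round(overlap_frac * nper))
    # symmetric Hann so time reversal exactly reverses the column layout
    f, t, sxx = sp_signal.spectrogram(
        x, fs=rate_hz, window=sp_signal.windows.hann(nper, sym=True),
        nperseg=nper, noverlap=nov, mode="magnitude")
    sel = f <= f_max_hz
    sxx = sxx[sel]
    f = f[sel]
    logmag = np.log10(sxx + 1e-8)
    rng = logmag.max() - logmag.min()
    norm = (logmag - logmag.min()) / rng if rng > 0 else np.zeros_like(logmag)
    cmap = matplotlib.colormaps[colormap]
    rgb = cmap(norm[::-1])[:, :, :3]          # low freq at the bottom row
    chans = [
        np.asarray(
            Image.fromarray(rgb[:, :, c].astype(np.float32), mode="F")
            .resize((224, 224), Image.BICUBIC),
            dtype=float)
        for c in range(3)
    ]
    pixels = np.clip(np.stack(chans, axis=-1), 0.0, 1.0)
    return SpectrogramImage(pixels=pixels, f_max_hz=f_max_hz,
                            window_s=window_s, overlap_frac=overlap_frac,
                            power_db=logmag, freqs_hz=f)
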