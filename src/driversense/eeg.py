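"""EEG features: channel-pair conditional entropy and band-power topomap images.

Two complementary feature families are extracted from the 14-channel montage:

* **Conditional entropy** H(Y|X) between every unordered electrode pair,
  derived from the plug-in mutual-information estimator I(X;Y) = H(Y) - H(Y|X)
  over a joint equal-width histogram.  Driving engages distributed brain
  systems, so cross-channel dependence is more informative than any single
  channel's spectrum; 14 electrodes give C(14,2) = 91 features per trial.
* **PSD topomaps**: per-channel mean power in the theta (4-7 Hz),
  alpha (7-13 Hz) and beta (13-30 Hz) bands is scatter-interpolated over the
  scalp disc, each band rendered into one RGB color channel (theta=red,
  alpha=green, beta=blue), alpha-blended in proportion to total band power,
  and resized to 224x224x3 for a CNN-style image embedder.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .io import EEG_CHANNELS, SignalStream, Trial, FeatureBlock

BANDS = {"theta": (4.0, 7.0), "alpha": (7.0, 13.0), "beta": (13.0, 30.0)}
#: band -> RGB color-channel index (theta=red, alpha=green, beta=blue)
BAND_COLOR = {"theta": 0, "alpha": 1, "beta": 2}


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float
    color_channel: str

    def __post_init__(self):
        if not self.lo_hz < self.hi_hz:
            raise ValueError("band lo must be below hi")


BAND_DEFINITIONS = (
    BandDefinition("theta", 4.0, 7.0, "R"),
    BandDefinition("alpha", 7.0, 13.0, "G"),
    BandDefinition("beta", 13.0, 30.0, "B"),
)


# ---------------------------------------------------------------------------
# Preprocessing

def bandpass_eeg(stream: SignalStream, lo_hz: float = 4.0,
                 hi_hz: float = 45.0, order: int = 4) -> SignalStream:
    """Zero-phase Butterworth band-pass (default 4-45 Hz: theta..low-gamma)."""
    nyq = stream.rate_hz / 2.0
    if hi_hz >= nyq:
        raise ValueError(f"hi_hz={hi_hz} must be below Nyquist ({nyq} Hz)")
    sos = sp_signal.butter(order, [lo_hz, hi_hz], btype="bandpass",
                           fs=stream.rate_hz, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, stream.samples, axis=1)
    return SignalStream(filtered, stream.rate_hz, stream.channel_names,
                        stream.modality)


def amplitude_reject(stream: SignalStream, z_thresh: float = 5.0
                     ) -> tuple[SignalStream, np.ndarray]:
    """Flag samples with |z| > ``z_thresh`` per channel, repair by linear
    interpolation across the flagged spans.

    A simple amplitude-threshold artifact rejection; returns the cleaned
    stream and the boolean mask of rejected samples.
    """
    if z_thresh <= 0:
        raise ValueError("z_thresh must be positive")
    x = stream.samples
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    mask = np.abs((x - mu) / sd) > z_thresh
    cleaned = x.copy()
    idx = np.arange(x.shape[1])
    for c in range(x.shape[0]):
        bad = mask[c]
        if not bad.any():
            continue
        if bad.all():
            raise ValueError(
                f"channel {stream.channel_names[c]}: every sample exceeds "
                f"z={z_thresh}; nothing left to interpolate from"
            )
        cleaned[c, bad] = np.interp(idx[bad], idx[~bad], x[c, ~bad])
    return (SignalStream(cleaned, stream.rate_hz, stream.channel_names,
                         stream.modality), mask)


# ---------------------------------------------------------------------------
# Mutual information / conditional entropy

@dataclass
class MutualInfoEstimate:
    """Plug-in MI estimate over a joint equal-width histogram, in bits."""

    I_xy: float
    H_y: float
    H_y_given_x: float
    bin_count: int
    joint_hist: np.ndarray

    def __post_init__(self):
        if self.I_xy < -1e-9:
            raise ValueError("mutual information cannot be negative")
        if abs(self.H_y_given_x - (self.H_y - self.I_xy)) > 1e-9:
            raise ValueError("H(Y|X) = H(Y) - I(X;Y) identity violated")


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: np.ndarray, y: np.ndarray,
                       bin_count: int = 16) -> MutualInfoEstimate:
    """Histogram plug-in estimate of I(X;Y), H(Y) and H(Y|X) in bits.

    Equal-width bins per variable over the observed range.  Entropies come
    from the same joint histogram, so I = H(X) + H(Y) - H(X,Y) and the
    conditional entropy H(Y|X) = H(X,Y) - H(X) satisfy the information
    identity I = H(Y) - H(Y|X) exactly; 0 log 0 is taken as 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2 * bin_count:
        raise ValueError(
            f"need at least 2*bin_count={2 * bin_count} samples, got {len(x)}"
        )
    joint, _, _ = np.histogram2d(x, y, bins=bin_count)
    p = joint / joint.sum()
    h_x = _entropy_bits(p.sum(axis=1))
    h_y = _entropy_bits(p.sum(axis=0))
    h_xy = _entropy_bits(p.ravel())
    i_xy = max(h_x + h_y - h_xy, 0.0)
    return MutualInfoEstimate(
        I_xy=i_xy, H_y=h_y, H_y_given_x=h_y - i_xy,
        bin_count=bin_count, joint_hist=joint,
    )


def conditional_entropy_vector(eeg_trial: SignalStream, bin_count: int = 16,
                               trial: Trial | None = None) -> FeatureBlock:
    """H(Y|X) for every unordered electrode pair (91 features for 14 channels).

    Pairs are ordered lexicographically by the canonical electrode list; Y is
    the later channel of the pair (H(Y|X) is not symmetric, so the direction
    must be pinned).
    """
    names = eeg_trial.channel_names
    if eeg_trial.modality != "eeg":
        raise ValueError("conditional entropy features require an EEG stream")
    if set(EEG_CHANNELS) <= set(names):
        order = [names.index(ch) for ch in EEG_CHANNELS]
    else:
        order = list(range(len(names)))
    values, labels = [], []
    for a, b in itertools.combinations(order, 2):
        est = mutual_information(eeg_trial.samples[a], eeg_trial.samples[b],
                                 bin_count=bin_count)
        values.append(est.H_y_given_x)
        labels.append(f"ce_{names[a]}_{names[b]}")
    ref = trial if trial is not None else Trial("?", "synthetic", 0.0, 1.0)
    return FeatureBlock(ref, "eeg", "entropy", np.array(values), tuple(labels))


# ---------------------------------------------------------------------------
# Band PSD and topomaps

def band_psd(eeg_trial: SignalStream, band: str | tuple[float, float],
             ) -> np.ndarray:
    """Mean in-band PSD per channel (Welch, 1 s Hann windows, 50% overlap).

    Sub-second slices fall back to a plain periodogram, which is the regime
    used when building per-window topomap sequences.
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    nyq = eeg_trial.rate_hz / 2.0
    if hi > nyq:
        raise ValueError(f"band upper edge {hi} Hz above Nyquist {nyq} Hz")
    x = eeg_trial.samples
    nper = int(round(eeg_trial.rate_hz))
    if x.shape[1] >= nper:
        f, psd = sp_signal.welch(x, fs=eeg_trial.rate_hz, window="hann",
                                 nperseg=nper, noverlap=nper // 2, axis=1)
    else:
        # zero-pad short windows so the band still contains spectral bins
        # (sub-second topomap-sequence windows can be a handful of samples)
        f, psd = sp_signal.periodogram(x, fs=eeg_trial.rate_hz, axis=1,
                                       nfft=max(x.shape[1], nper))
    sel = (f >= lo) & (f <= hi)
    if not sel.any():
        raise ValueError(f"no spectral bins inside [{lo}, {hi}] Hz")
    return psd[:, sel].mean(axis=1)


_MONTAGE_CACHE: dict[tuple[str, ...], np.ndarray] = {}


def montage_positions(channels: tuple[str, ...] = EEG_CHANNELS) -> np.ndarray:
    """2-D unit-disc electrode positions (azimuthal-equidistant projection
    of the standard 10-20 sphere; nose along +y)."""
    channels = tuple(channels)
    if channels in _MONTAGE_CACHE:
        return _MONTAGE_CACHE[channels]
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage name is stable across mne versions; newer ones alias it
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos3 = montage.get_positions()["ch_pos"]
    pts = []
    for ch in channels:
        v = np.asarray(pos3[ch], dtype=float)
        v = v / np.linalg.norm(v)
        polar = np.arccos(np.clip(v[2], -1, 1))       # angle from vertex
        az_norm = np.hypot(v[0], v[1])
        if az_norm < 1e-12:
            pts.append((0.0, 0.0))
            continue
        pts.append((polar * v[0] / az_norm, polar * v[1] / az_norm))
    pts = np.asarray(pts)
    # scale so the outermost electrode sits at radius 0.82 of the head disc
    pts *= 0.82 / np.max(np.linalg.norm(pts, axis=1))
    _MONTAGE_CACHE[channels] = pts
    return pts


@dataclass
class TopomapImage:
    """224x224x3 scalp-map raster; zero outside the head disc."""

    pixels: np.ndarray
    band_weights: np.ndarray
    montage_positions: np.ndarray

    def __post_init__(self):
        if self.pixels.shape != (224, 224, 3):
            raise ValueError(f"expected 224x224x3, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixels must lie in [0, 1]")


def _disc_mask(n: int) -> np.ndarray:
    xs = np.linspace(-1, 1, n)
    gx, gy = np.meshgrid(xs, xs)
    return gx ** 2 + gy ** 2 <= 1.0


def _idw_disc_grid(values: np.ndarray, positions: np.ndarray,
                   grid_n: int = 32, power: float = 2.0) -> np.ndarray:
    """Inverse-distance-weighted interpolation of scattered electrode values
    onto a grid covering the unit disc (zero outside)."""
    xs = np.linspace(-1, 1, grid_n)
    gx, gy = np.meshgrid(xs, xs)
    d2 = ((gx[..., None] - positions[:, 0]) ** 2
          + (gy[..., None] - positions[:, 1]) ** 2)
    w = 1.0 / np.maximum(d2, 1e-12) ** (power / 2.0)
    img = (w * values).sum(axis=-1) / w.sum(axis=-1)
    return np.where(_disc_mask(grid_n), img, 0.0)


def _bicubic_resize_2d(img: np.ndarray, size: int = 224) -> np.ndarray:
    from PIL import Image

    return np.asarray(
        Image.fromarray(img.astype(np.float32), mode="F")
        .resize((size, size), Image.BICUBIC),
        dtype=float,
    )


def topomap_rgb(psd_theta: np.ndarray, psd_alpha: np.ndarray,
                psd_beta: np.ndarray,
                montage: np.ndarray | None = None,
                grid_n: int = 32, idw_power: float = 2.0) -> TopomapImage:
    """Encode three band-PSD vectors as one RGB scalp image.

    Per band: IDW-interpolate the 14 electrode values onto the head disc,
    normalize the band image by its own maximum, and place it in that band's
    color channel.  The three channels are alpha-blended with weights
    proportional to total band power (largest weight scaled to 1), so the
    color balance carries the relative band energies while spatial structure
    within a channel carries topography.  Scaling all bands by a common
    positive factor leaves the image unchanged.
    """
    vecs = [np.asarray(v, dtype=float).ravel() for v in
            (psd_theta, psd_alpha, psd_beta)]
    if any(not np.all(np.isfinite(v)) for v in vecs):
        raise ValueError("band PSD vectors must be finite")
    if any(v.min() < 0 for v in vecs):
        raise ValueError("band PSD vectors must be non-negative")
    totals = np.array([v.sum() for v in vecs])
    if totals.max() == 0:
        raise ValueError("all-zero band PSDs: topomap normalization undefined")
    if montage is None:
        montage = montage_positions()
    if any(len(v) != len(montage) for v in vecs):
        raise ValueError("each band vector needs one value per electrode")
    weights = totals / totals.max()
    pixels = np.zeros((224, 224, 3))
    mask224 = _disc_mask(224)
    for band_idx, vec in enumerate(vecs):
        if vec.max() == 0:
            continue                      # silent band -> channel stays 0
        grid = _idw_disc_grid(vec, montage, grid_n=grid_n, power=idw_power)
        grid = grid / grid.max()
        chan = _bicubic_resize_2d(grid, 224) * weights[band_idx]
        pixels[:, :, band_idx] = np.where(mask224, np.clip(chan, 0.0, 1.0), 0.0)
    return TopomapImage(pixels=pixels, band_weights=weights,
                        montage_positions=montage)


def trial_topomap(eeg_trial: SignalStream, **kwargs) -> TopomapImage:
    """Whole-trial topomap from the three band-PSD vectors."""
    return topomap_rgb(band_psd(eeg_trial, "theta"),
                       band_psd(eeg_trial, "alpha"),
                       band_psd(eeg_trial, "beta"), **kwargs)


def topomap_sequence(eeg_trial: SignalStream, windows_per_second: float = 1.0,
                     **kwargs) -> list[TopomapImage]:
    """One topomap per contiguous non-overlapping window, chronological.

    Attention trials use one image per second; 2-s incident trials use 30
    images per second (60 images), trading window length for temporal
    resolution in the downstream sequence model.
    """
    n_windows = windows_per_second * eeg_trial.duration_s
    if abs(n_windows - round(n_windows)) > 1e-6 or round(n_windows) < 1:
        raise ValueError(
            f"windows_per_second x duration must be a positive integer, "
            f"got {n_windows}"
        )
    n_windows = int(round(n_windows))
    win_len = eeg_trial.n_samples // n_windows
    if win_len < 2:
        raise ValueError("window shorter than 2 samples")
    images = []
    for k in range(n_windows):
        sl = SignalStream(
            eeg_trial.samples[:, k * win_len:(k + 1) * win_len],
            eeg_trial.rate_hz, eeg_trial.channel_names, eeg_trial.modality,
        )
        images.append(trial_topomap(sl, **kwargs))
    return images
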