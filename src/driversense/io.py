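"""Data model and file I/O for multimodal driver-monitoring recordings.

A :class:`Recording` bundles one subject's synchronized sensor streams
(14-channel EEG at 128 Hz, single-channel PPG and GSR at 51.2 Hz) with the
per-frame facial-landmark table.  Trials are labelled time slices of a
recording; feature extractors consume trial-aligned slices and emit
:class:`FeatureBlock` objects that accumulate into a flat feature table.

On-disk formats are deliberately plain text: signal tables are CSV with a
time column plus one column per channel, landmark tables are long-format
CSV (frame, point, x, y, face_w, face_h), and the manifest/config are JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical 14-electrode montage of the consumer EEG headset, in the fixed
#: order used everywhere downstream (channel-pair features, topomaps).
EEG_CHANNELS: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "T7", "T8", "P7", "P8", "O1", "O2",
)

EEG_RATE_HZ = 128.0
PPG_GSR_RATE_HZ = 51.2

VALID_MODALITIES = ("eeg", "ppg", "gsr")
VALID_DATASET_TAGS = ("kitti", "lisa", "synthetic")


def round_half_away(x: float) -> int:
    """Round half away from zero (2 s at 51.2 Hz -> round(102.4) = 102)."""
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class SignalStream:
    """One modality's samples: (n_channels, n_samples) array plus metadata."""

    samples: np.ndarray
    rate_hz: float
    channel_names: tuple[str, ...]
    modality: str

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.modality not in VALID_MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.channel_names = tuple(self.channel_names)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def require_montage(self) -> None:
        """Raise unless this is the full 14-channel EEG montage."""
        if self.modality != "eeg":
            raise ValueError("montage features require an EEG stream")
        missing = [ch for ch in EEG_CHANNELS if ch not in self.channel_names]
        if missing:
            raise ValueError(f"EEG stream is missing electrode(s): {missing}")
        if len(self.channel_names) != len(EEG_CHANNELS):
            raise ValueError(
                f"expected {len(EEG_CHANNELS)} EEG channels, "
                f"got {len(self.channel_names)}"
            )

    def slice_seconds(self, t_start_s: float, t_end_s: float) -> "SignalStream":
        """Trial-aligned slice; length = round_half_away(duration * rate)."""
        if t_end_s <= t_start_s:
            raise ValueError("t_end_s must exceed t_start_s")
        i0 = round_half_away(t_start_s * self.rate_hz)
        n = round_half_away((t_end_s - t_start_s) * self.rate_hz)
        if i0 < 0 or i0 + n > self.n_samples:
            raise ValueError(
                f"slice [{t_start_s}, {t_end_s}] s outside the "
                f"{self.duration_s:.2f} s recording"
            )
        return SignalStream(
            self.samples[:, i0:i0 + n], self.rate_hz,
            self.channel_names, self.modality,
        )


@dataclass
class LandmarkFrame:
    """49 facial-landmark pixel coordinates for one video frame."""

    points: np.ndarray            # (49, 2)
    face_w: float
    face_h: float
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (49, 2):
            raise ValueError(f"expected 49 (x, y) points, got {self.points.shape}")
        if self.face_w < 50 or self.face_h < 50:
            raise ValueError(
                f"face box {self.face_w:.0f}x{self.face_h:.0f} below the "
                "50x50 pixel minimum face size"
            )


@dataclass
class Trial:
    """A labelled time slice of one subject's recording."""

    subject_id: str
    dataset_tag: str
    t_start_s: float
    t_end_s: float
    attention_label: str | None = None     # {"low", "high"}
    hazard_label: str | None = None        # {"hazardous", "non_hazardous"}

    def __post_init__(self) -> None:
        if self.dataset_tag not in VALID_DATASET_TAGS:
            raise ValueError(f"unknown dataset_tag {self.dataset_tag!r}")
        if self.t_end_s <= self.t_start_s:
            raise ValueError("trial must have positive duration")
        if self.hazard_label is not None:
            if abs(self.duration_s - 2.0) > 1e-9:
                raise ValueError(
                    f"incident trials are exactly 2 s long, got {self.duration_s} s"
                )
        if self.attention_label not in (None, "low", "high"):
            raise ValueError(f"bad attention_label {self.attention_label!r}")
        if self.hazard_label not in (None, "hazardous", "non_hazardous"):
            raise ValueError(f"bad hazard_label {self.hazard_label!r}")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class FeatureBlock:
    """Named per-trial feature vector with modality + method provenance."""

    trial_ref: Trial
    modality: str
    method: str
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.names = tuple(self.names)
        if len(self.values) != len(self.names):
            raise ValueError(
                f"{len(self.values)} values vs {len(self.names)} names"
            )
        if not np.all(np.isfinite(self.values)):
            bad = [self.names[i] for i in np.flatnonzero(~np.isfinite(self.values))]
            raise ValueError(f"non-finite feature value(s): {bad[:5]}")


@dataclass
class Recording:
    """One subject's synchronized streams plus landmark frames."""

    subject_id: str
    streams: dict[str, SignalStream] = field(default_factory=dict)
    landmarks: list[LandmarkFrame] = field(default_factory=list)
    fps: float = 30.0

    def landmark_slice(self, t_start_s: float, t_end_s: float) -> list[LandmarkFrame]:
        return [f for f in self.landmarks if t_start_s <= f.timestamp_s < t_end_s]


@dataclass
class TrialSlices:
    """Trial-aligned stream slices and landmark frames for one trial."""

    trial: Trial
    streams: dict[str, SignalStream]
    landmarks: list[LandmarkFrame]


def segment_trials(recording: Recording, trial_specs: Sequence[Trial]) -> list[TrialSlices]:
    """Slice every stream of ``recording`` to each trial's time span.

    Slice lengths follow round-half-away-from-zero on duration x rate, so a
    2 s incident yields 256 EEG samples and 102 PPG/GSR samples.
    """
    out = []
    for trial in trial_specs:
        streams = {
            name: s.slice_seconds(trial.t_start_s, trial.t_end_s)
            for name, s in recording.streams.items()
        }
        out.append(TrialSlices(
            trial=trial,
            streams=streams,
            landmarks=recording.landmark_slice(trial.t_start_s, trial.t_end_s),
        ))
    return out


# ---------------------------------------------------------------------------
# File I/O

def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write an RGB float image in [0, 1] as 8-bit PNG (round(255 x value))."""
    from PIL import Image

    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {pixels.shape}")
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("pixels must lie in [0, 1]")
    arr = np.round(255.0 * pixels).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, format="PNG")


def read_image_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG back to RGB floats in [0, 1]."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float)
    return arr / 255.0


def write_signal_table(stream: SignalStream, path: str | Path) -> None:
    t = np.arange(stream.n_samples) / stream.rate_hz
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(stream.channel_names):
        df[ch] = stream.samples[i]
    df.to_csv(path, index=False, float_format="%.17g")


def read_signal_table(path: str | Path, rate_hz: float, modality: str,
                      expected_channels: Sequence[str] | None = None) -> SignalStream:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing 'time_s' column")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: non-monotone time column")
        implied = 1.0 / np.median(np.diff(t))
        if abs(implied - rate_hz) / rate_hz > 0.01:
            raise ValueError(
                f"{path}: time column implies {implied:.3f} Hz, manifest says {rate_hz}"
            )
    channels = [c for c in df.columns if c != "time_s"]
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in channels]
        if missing:
            raise ValueError(f"{path}: missing channel(s) {missing}")
        channels = list(expected_channels)
    return SignalStream(df[channels].to_numpy().T, rate_hz, tuple(channels), modality)


def write_landmark_table(frames: Sequence[LandmarkFrame], path: str | Path) -> None:
    rows = []
    for k, f in enumerate(frames):
        for p in range(49):
            rows.append((k, p, f.points[p, 0], f.points[p, 1],
                         f.face_w, f.face_h, f.timestamp_s))
    pd.DataFrame(
        rows, columns=["frame", "point", "x", "y", "face_w", "face_h", "timestamp_s"],
    ).to_csv(path, index=False, float_format="%.17g")


def read_landmark_table(path: str | Path) -> list[LandmarkFrame]:
    df = pd.read_csv(path, float_precision="round_trip")
    frames = []
    for k, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("point")
        if len(grp) != 49:
            raise ValueError(f"{path}: frame {k} has {len(grp)} points, expected 49")
        frames.append(LandmarkFrame(
            points=grp[["x", "y"]].to_numpy(),
            face_w=float(grp["face_w"].iloc[0]),
            face_h=float(grp["face_h"].iloc[0]),
            timestamp_s=float(grp["timestamp_s"].iloc[0]),
        ))
    return frames


def write_recording(recording: Recording, out_dir: str | Path) -> Path:
    """Write streams, landmarks and a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subject_id": recording.subject_id, "fps": recording.fps,
                      "streams": {}}
    for name, s in recording.streams.items():
        fname = f"{recording.subject_id}_{name}.csv"
        write_signal_table(s, out / fname)
        manifest["streams"][name] = {
            "file": fname, "rate_hz": s.rate_hz, "modality": s.modality,
            "channels": list(s.channel_names),
        }
    if recording.landmarks:
        fname = f"{recording.subject_id}_landmarks.csv"
        write_landmark_table(recording.landmarks, out / fname)
        manifest["landmarks"] = fname
    mpath = out / f"{recording.subject_id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def read_recording(manifest_path: str | Path) -> Recording:
    """Load a recording from its JSON manifest (streams + landmark table)."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    rec = Recording(subject_id=manifest["subject_id"], fps=manifest.get("fps", 30.0))
    for name, meta in manifest["streams"].items():
        expected = meta["channels"] if meta["modality"] == "eeg" else None
        rec.streams[name] = read_signal_table(
            mpath.parent / meta["file"], meta["rate_hz"], meta["modality"],
            expected_channels=expected,
        )
        if meta["modality"] == "eeg" and len(meta["channels"]) == 14:
            rec.streams[name].require_montage()
    if "landmarks" in manifest:
        rec.landmarks = read_landmark_table(mpath.parent / manifest["landmarks"])
    return rec
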