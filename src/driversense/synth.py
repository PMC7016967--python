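"""Synthetic multimodal recordings with controllable class structure.

The generator emulates the statistical structure the pipeline assumes,
without pretending to be a biophysical forward model:

* **EEG** (14 channels, 128 Hz): per-channel 1/f background plus shared
  narrowband theta/alpha/beta oscillations with fixed scalp profiles
  (alpha occipital, beta frontal, theta fronto-midline), so channels are
  correlated as real scalp recordings are.  High-attention / hazardous
  trials shift alpha power down and beta power up multiplicatively by the
  effect size, modulated by a per-subject gain.
* **PPG** (51.2 Hz): a periodic pulse waveform (systolic peak + dicrotic
  notch) whose RR intervals jitter by a controllable amount; attention
  raises heart rate and suppresses variability.
* **GSR** (51.2 Hz): slow tonic drift plus Poisson-timed skin-conductance
  responses (fast rise, exponential decay); attention raises the SCR rate.
* **Landmarks** (30 fps): a canonical symmetric 49-point face with smooth
  brow/mouth expression oscillations whose magnitude grows with the effect
  for positive-class trials, plus per-frame jitter.

Effects are injected in physiological observables (band power, RR
variability, SCR rate, expression magnitude), never directly in features,
so every extraction stage is genuinely exercised.  One global seed fans out
to per-subject / per-trial / per-modality sub-streams through
``np.random.SeedSequence`` spawn keys, so any trial can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

from .io import (EEG_CHANNELS, EEG_RATE_HZ, PPG_GSR_RATE_HZ, LandmarkFrame,
                 Recording, SignalStream, Trial, TrialSlices)

# fixed scalp amplitude profiles per band (canonical electrode order)
_PROFILES = {
    # AF3  AF4   F3   F4   F7   F8  FC5  FC6   T7   T8   P7   P8   O1   O2
    "theta": np.array([1.0, 1.0, 0.9, 0.9, 0.7, 0.7, 0.8, 0.8,
                       0.5, 0.5, 0.4, 0.4, 0.3, 0.3]),
    "alpha": np.array([0.3, 0.3, 0.4, 0.4, 0.4, 0.4, 0.5, 0.5,
                       0.7, 0.7, 1.0, 1.0, 1.2, 1.2]),
    "beta": np.array([0.9, 0.9, 0.8, 0.8, 0.7, 0.7, 0.8, 0.8,
                      0.6, 0.6, 0.5, 0.5, 0.4, 0.4]),
}
_CENTER_HZ = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (14.0, 28.0)}
_BASE_AMP = {"theta": 0.6, "alpha": 1.0, "beta": 0.5}


@dataclass
class GeneratorConfig:
    """Study-scale defaults: 12 subjects, 35 attention trials each (420
    total), 70 two-second incident trials each of which 30 are hazardous."""

    n_subjects: int = 12
    trials_per_subject: int = 35
    incidents_per_subject: int = 70
    hazardous_per_subject: int = 30
    attention_effect: float = 1.0
    hazard_effect: float = 1.0
    subject_variability: float = 0.2
    base_hr_bpm: float = 72.0
    hrv_s: float = 0.03
    scr_rate_per_min: float = 3.0
    attention_trial_s: float = 14.0
    fps: float = 30.0
    landmark_jitter_px: float = 0.5
    expression_amp_px: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _pink_noise(n: int, rng: np.random.Generator, rate: float) -> np.ndarray:
    """1/f-power background via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    spec /= np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _narrowband(n: int, rng: np.random.Generator, rate: float,
                lo: float, hi: float) -> np.ndarray:
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_eeg(positive: bool, effect: float, subject_gain: float,
            duration_s: float, rng: np.random.Generator,
            rate_hz: float = EEG_RATE_HZ) -> tuple[SignalStream, dict]:
    """14-channel EEG stream; positive-class trials get alpha down / beta up.

    Returns the stream and a ground-truth dict of realized band gains.
    """
    if duration_s < 2.0:
        duration_s = max(duration_s, 2.0 / rate_hz * 2)
    n = int(round(duration_s * rate_hz))
    shift = 0.6 * effect * subject_gain
    gains = {"theta": 1.0,
             "alpha": float(np.exp(-shift)) if positive else 1.0,
             "beta": float(np.exp(shift)) if positive else 1.0}
    trial_jitter = float(np.exp(rng.normal(0.0, 0.15)))
    samples = np.empty((14, n))
    shared = {b: _narrowband(n, rng, rate_hz, *_CENTER_HZ[b]) for b in _PROFILES}
    for c in range(14):
        x = 0.8 * _pink_noise(n, rng, rate_hz)
        for b in _PROFILES:
            amp = (_BASE_AMP[b] * gains[b] * trial_jitter
                   * _PROFILES[b][c] * subject_gain)
            x = x + amp * shared[b]
        x = x + 0.2 * rng.standard_normal(n)
        samples[c] = x
    stream = SignalStream(samples, rate_hz, EEG_CHANNELS, "eeg")
    return stream, {"band_gains": gains, "trial_jitter": trial_jitter}


def gen_ppg(hr_bpm: float, hrv_level: float, duration_s: float,
            rng: np.random.Generator, rate_hz: float = PPG_GSR_RATE_HZ,
            jitter_mode: str = "gaussian") -> tuple[SignalStream, dict]:
    """Pulse train with controllable rate and RR jitter.

    ``hrv_level`` is the RR jitter scale in seconds.  ``jitter_mode``
    'gaussian' draws i.i.d. N(0, hrv_level) RR perturbations;
    'alternating' toggles ±hrv_level so every successive RR difference is
    exactly 2*hrv_level (useful to pin pNN50 at 0 or 1 by construction).
    """
    if not 40 <= hr_bpm <= 180:
        raise ValueError("hr_bpm must lie in [40, 180]")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rr0 = 60.0 / hr_bpm
    beats = []
    tk = 0.3
    k = 0
    while tk < duration_s:
        beats.append(tk)
        if jitter_mode == "alternating":
            jit = hrv_level if k % 2 == 0 else -hrv_level
        else:
            jit = float(rng.normal(0.0, hrv_level)) if hrv_level > 0 else 0.0
        tk += max(rr0 + jit, 0.3)
        k += 1
    x = np.zeros(n)
    for tb in beats:
        x += np.exp(-0.5 * ((t - tb) / 0.06) ** 2)          # systolic peak
        x += 0.25 * np.exp(-0.5 * ((t - tb - 0.25) / 0.08) ** 2)  # dicrotic
    x += 0.05 * np.sin(2 * np.pi * 0.1 * t)                 # baseline wander
    x += 0.01 * rng.standard_normal(n)
    stream = SignalStream(x, rate_hz, ("ppg",), "ppg")
    return stream, {"beat_times_s": np.asarray(beats), "hr_bpm": hr_bpm}


def gen_gsr(scr_rate_per_min: float, duration_s: float,
            rng: np.random.Generator, rate_hz: float = PPG_GSR_RATE_HZ,
            scr_amp: float = 0.3) -> tuple[SignalStream, dict]:
    """Tonic skin-conductance drift plus Poisson-timed phasic SCR bursts."""
    if scr_rate_per_min < 0:
        raise ValueError("scr rate must be non-negative")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    x = 2.0 + 0.02 * np.sin(2 * np.pi * t / 60.0) + 0.002 * t
    n_events = rng.poisson(scr_rate_per_min * duration_s / 60.0)
    times = np.sort(rng.uniform(1.0, max(duration_s - 3.0, 1.0), n_events))
    amps = scr_amp * np.exp(rng.normal(0.0, 0.3, n_events))
    for te, a in zip(times, amps):
        dt = t - te
        rise = np.clip(dt / 0.7, 0.0, 1.0)                  # 0.7 s linear rise
        decay = np.where(dt > 0.7, np.exp(-(dt - 0.7) / 2.5), 1.0)
        x += a * rise * decay * (dt > 0)
    x += 0.002 * rng.standard_normal(n)
    stream = SignalStream(x, rate_hz, ("gsr",), "gsr")
    return stream, {"scr_times_s": times, "scr_amps": amps}


# canonical symmetric 49-point face in a 200 x 240 pixel box (y down)
def _base_face() -> np.ndarray:
    pts = np.zeros((49, 2))
    pts[0:5] = [(30, 58), (44, 53), (57.5, 50), (71, 53), (85, 56)]     # L brow
    pts[5:10] = [(115, 56), (129, 53), (142.5, 50), (156, 53), (170, 58)]
    pts[10:14] = [(100, 70), (100, 85), (100, 100), (100, 115)]         # bridge
    pts[14:19] = [(80, 128), (90, 130), (100, 132), (110, 130), (120, 128)]
    pts[19:25] = [(40, 80), (53, 74), (67, 74), (80, 80), (53, 86), (67, 86)]
    pts[25:31] = [(160, 80), (147, 74), (133, 74), (120, 80), (147, 86), (133, 86)]
    pts[31:43] = [(60, 180), (73, 172), (86, 167), (100, 165), (114, 167),
                  (127, 172), (140, 180), (127, 188), (114, 193), (100, 195),
                  (86, 193), (73, 188)]
    pts[43:49] = [(70, 180), (100, 174), (130, 180), (115, 184), (100, 186),
                  (85, 184)]
    return pts


#: public handle on the canonical neutral face layout
base_face_points = _base_face

BASE_FACE_W, BASE_FACE_H = 200.0, 240.0
_BROW_IDX = list(range(0, 10))
_LOWER_MOUTH_IDX = [38, 39, 40, 41, 42, 46, 47, 48]


def gen_landmarks(positive: bool, effect: float, n_frames: int,
                  rng: np.random.Generator, fps: float = 30.0,
                  t_start_s: float = 0.0, expression_amp_px: float = 2.0,
                  jitter_px: float = 0.5) -> list[LandmarkFrame]:
    """Landmark-frame sequence: smooth brow-raise / mouth-open oscillation
    with label-dependent magnitude, plus per-frame jitter."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    base = _base_face()
    amp = expression_amp_px * (1.0 + 2.0 * effect * (1.0 if positive else 0.0))
    f_expr = 0.4 + 0.2 * rng.random()
    phase = rng.uniform(0, 2 * np.pi)
    frames = []
    for k in range(n_frames):
        t = k / fps
        env = np.sin(2 * np.pi * f_expr * t + phase)
        pts = base.copy()
        pts[_BROW_IDX, 1] -= amp * env                     # brow raise
        pts[_LOWER_MOUTH_IDX, 1] += 1.5 * amp * max(env, 0.0)  # mouth open
        if jitter_px > 0:
            pts += rng.normal(0.0, jitter_px, pts.shape)
        frames.append(LandmarkFrame(points=pts, face_w=BASE_FACE_W,
                                    face_h=BASE_FACE_H,
                                    timestamp_s=t_start_s + t))
    return frames


@dataclass
class SubjectParams:
    subject_gain: float
    hr_base_bpm: float
    hrv_base_s: float
    scr_base_per_min: float


@dataclass
class TrialRecord:
    """Manifest entry: labels plus the ground-truth sidecar for oracle tests."""

    trial: Trial
    subject_idx: int
    trial_idx: int
    task: str                      # {"attention", "incident"}
    truth: dict = field(default_factory=dict)


class SyntheticDataset:
    """Lazily generated multimodal dataset at the configured cohort scale.

    The manifest (labels, subjects, trial spans) is built eagerly; signal
    samples are synthesized on demand per trial from counter-derived seeds,
    so iterating a 420-trial cohort never holds more than one trial's
    samples in memory.
    """

    def __init__(self, config: GeneratorConfig):
        self.config = config
        self.subject_ids = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
        self.subject_params = [self._subject_params(i)
                               for i in range(config.n_subjects)]
        self.records: list[TrialRecord] = []
        self._build_manifest()

    def _subject_params(self, i: int) -> SubjectParams:
        rng = _rng(self.config.seed, i, 0, 0)
        return SubjectParams(
            subject_gain=float(np.exp(rng.normal(0.0, self.config.subject_variability))),
            hr_base_bpm=float(np.clip(rng.normal(self.config.base_hr_bpm, 5.0),
                                      45, 170)),
            hrv_base_s=float(self.config.hrv_s * np.exp(rng.normal(0.0, 0.2))),
            scr_base_per_min=float(max(
                self.config.scr_rate_per_min * np.exp(rng.normal(0.0, 0.2)), 0.1)),
        )

    def _build_manifest(self) -> None:
        cfg = self.config
        tags = ("kitti", "lisa")
        for s in range(cfg.n_subjects):
            rng = _rng(cfg.seed, s, 0, 1)
            # attention trials: balanced low/high, shuffled per subject
            n_att = cfg.trials_per_subject
            labels = np.array(["low", "high"])[
                rng.permutation(np.arange(n_att) % 2)]
            for k in range(n_att):
                t0 = k * cfg.attention_trial_s
                trial = Trial(self.subject_ids[s], tags[k % 2], t0,
                              t0 + cfg.attention_trial_s,
                              attention_label=str(labels[k]))
                self.records.append(TrialRecord(trial, s, k, "attention"))
            # incident trials: fixed hazardous count, shuffled order
            haz = np.array(["hazardous"] * cfg.hazardous_per_subject
                           + ["non_hazardous"]
                           * (cfg.incidents_per_subject - cfg.hazardous_per_subject))
            rng.shuffle(haz)
            for k in range(cfg.incidents_per_subject):
                t0 = k * 2.0
                trial = Trial(self.subject_ids[s], tags[k % 2], t0, t0 + 2.0,
                              hazard_label=str(haz[k]))
                self.records.append(TrialRecord(trial, s, k, "incident"))

    # -- per-trial synthesis ------------------------------------------------

    def trial_streams(self, rec: TrialRecord) -> TrialSlices:
        cfg = self.config
        p = self.subject_params[rec.subject_idx]
        dur = rec.trial.duration_s
        task_code = 0 if rec.task == "attention" else 1
        if rec.task == "attention":
            positive = rec.trial.attention_label == "high"
            effect = cfg.attention_effect
        else:
            positive = rec.trial.hazard_label == "hazardous"
            effect = cfg.hazard_effect
        key = (rec.subject_idx, task_code, rec.trial_idx)

        eeg, eeg_truth = gen_eeg(positive, effect, p.subject_gain, dur,
                                 _rng(cfg.seed, *key, 1))
        hr = p.hr_base_bpm + (8.0 * effect if positive and task_code == 0 else 0.0)
        hrv = p.hrv_base_s * (np.exp(-0.5 * effect) if positive and task_code == 0
                              else 1.0)
        ppg, ppg_truth = gen_ppg(float(np.clip(hr, 40, 180)), hrv, dur,
                                 _rng(cfg.seed, *key, 2))
        scr = p.scr_base_per_min + (2.0 * effect if positive and task_code == 0
                                    else 0.0)
        gsr, gsr_truth = gen_gsr(scr, dur, _rng(cfg.seed, *key, 3))
        n_frames = max(int(round(dur * cfg.fps)), 2)
        frames = gen_landmarks(positive, effect, n_frames,
                               _rng(cfg.seed, *key, 4), fps=cfg.fps,
                               t_start_s=rec.trial.t_start_s,
                               expression_amp_px=cfg.expression_amp_px,
                               jitter_px=cfg.landmark_jitter_px)
        rec.truth = {"eeg": eeg_truth, "ppg": ppg_truth, "gsr": gsr_truth,
                     "positive": positive, "effect": effect}
        return TrialSlices(trial=rec.trial,
                           streams={"eeg": eeg, "ppg": ppg, "gsr": gsr},
                           landmarks=frames)

    def iter_trials(self, task: str = "attention"):
        for rec in self.records:
            if rec.task == task:
                yield rec, self.trial_streams(rec)

    def manifest(self, task: str | None = None) -> list[TrialRecord]:
        return [r for r in self.records if task is None or r.task == task]

    # -- disk layout --------------------------------------------------------

    def write(self, out_dir: str | Path, task: str = "attention",
              subjects: list[int] | None = None) -> Path:
        """Write per-subject recordings (concatenated trials) + trial table.

        Returns the dataset root.  Each subject's trials are laid back to
        back so the trial spans in ``trials.csv`` index into the recording.
        """
        import json
        import pandas as pd
        from .io import write_recording

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        subjects = subjects if subjects is not None else range(self.config.n_subjects)
        rows = []
        for s in subjects:
            recs = [r for r in self.records
                    if r.subject_idx == s and r.task == task]
            streams: dict[str, list[np.ndarray]] = {}
            frames: list[LandmarkFrame] = []
            meta = None
            for r in recs:
                ts = self.trial_streams(r)
                for name, st in ts.streams.items():
                    streams.setdefault(name, []).append(st.samples)
                    meta = meta or {}
                frames.extend(ts.landmarks)
                rows.append({
                    "subject_id": r.trial.subject_id,
                    "dataset_tag": r.trial.dataset_tag,
                    "task": task,
                    "t_start_s": r.trial.t_start_s,
                    "t_end_s": r.trial.t_end_s,
                    "attention_label": r.trial.attention_label or "",
                    "hazard_label": r.trial.hazard_label or "",
                })
            rec_obj = Recording(subject_id=self.subject_ids[s], fps=self.config.fps)
            proto = self.trial_streams(recs[0]).streams
            for name, chunks in streams.items():
                rec_obj.streams[name] = SignalStream(
                    np.concatenate(chunks, axis=1), proto[name].rate_hz,
                    proto[name].channel_names, proto[name].modality)
            rec_obj.landmarks = frames
            write_recording(rec_obj, out)
        pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
        (out / "generator_config.json").write_text(
            json.dumps(self.config.to_dict(), indent=2))
        return out


def gen_dataset(config: GeneratorConfig | None = None, **overrides
                ) -> SyntheticDataset:
    """Build a lazily-synthesized dataset at the configured cohort scale."""
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    return SyntheticDataset(config)
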