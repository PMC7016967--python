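"""End-to-end pipeline: synthesize/load -> extract -> classify -> report.

A :class:`PipelineConfig` names the task (attention or incident), the
modalities and per-modality feature methods, the classifier (ELM on
per-trial vectors, LSTM on per-window sequences), the CV scheme and the
seed.  ``run_pipeline`` chains everything under leave-one-subject-out CV
and writes the feature table, per-fold metrics and a summary.

PPG and GSR are refused for the 2-s incident task: those signals take
several seconds to react physiologically, so they carry no usable
information at that temporal resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cardio, eeg as eeg_mod, face as face_mod
from .classify import ELMClassifier, LSTMClassifier, loso_cv
from .embedding import get_embedder, resize_to_input
from .io import TrialSlices
from .synth import GeneratorConfig, SyntheticDataset, gen_dataset

#: feature methods per modality
DEFAULT_METHODS = {"eeg": "entropy", "ppg": "hrv_stat",
                   "gsr": "hrv_stat", "face": "geometric"}


@dataclass
class PipelineConfig:
    task: str = "attention"                    # {"attention", "incident"}
    modalities: tuple[str, ...] = ("eeg",)
    methods: dict = field(default_factory=lambda: dict(DEFAULT_METHODS))
    classifier: str = "elm"                    # {"elm", "lstm"}
    embedder: str = "stub"
    pca_k: int = 30
    seq_pca_k: int = 60
    scaler_scope: str = "train_only"           # "global" = paper-faithful
    n_hidden: int = 170
    face_frame_stride: int = 6
    seed: int = 0
    generator: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.task not in ("attention", "incident"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.classifier not in ("elm", "lstm"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        bad = [m for m in self.modalities if m not in DEFAULT_METHODS]
        if bad:
            raise ValueError(f"unknown modalities {bad}")
        if self.task == "incident":
            low_res = [m for m in self.modalities if m in ("ppg", "gsr")]
            if low_res:
                raise ValueError(
                    f"{low_res} cannot be used for the 2-s incident task: "
                    "PPG and GSR do not provide such a fine temporal "
                    "resolution (they take seconds to react); use eeg/face")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modalities"] = list(self.modalities)
        return d


def _label_of(trial, task: str) -> str:
    return trial.attention_label if task == "attention" else trial.hazard_label


def extract_trial_features(ts: TrialSlices, modality: str, method: str,
                           embedder) -> tuple[np.ndarray, list[str]]:
    """One trial's feature vector for a (modality, method) pair."""
    trial = ts.trial
    if modality == "eeg":
        stream = eeg_mod.bandpass_eeg(ts.streams["eeg"])
        if method == "entropy":
            block = eeg_mod.conditional_entropy_vector(stream, trial=trial)
            return block.values, list(block.names)
        if method == "deep_psd":
            img = eeg_mod.trial_topomap(stream)
            vec = embedder.embed(img.pixels)
            return vec, [f"psd_img_{i:04d}" for i in range(len(vec))]
    elif modality == "ppg":
        x = ts.streams["ppg"].samples[0]
        rate = ts.streams["ppg"].rate_hz
        if method == "hrv_stat":
            feats = cardio.ppg_features(x, rate)
            vals = np.concatenate([[feats.hr_bpm, feats.pnn50], feats.stat6])
            return vals, (["ppg_hr", "ppg_pnn50"]
                          + [f"ppg_stat{i + 1}" for i in range(6)])
        if method == "spectro_deep":
            img = cardio.spectrogram_image(x, rate, f_max_hz=5.0)
            vec = embedder.embed(img.pixels)
            return vec, [f"ppg_spec_{i:04d}" for i in range(len(vec))]
    elif modality == "gsr":
        x = ts.streams["gsr"].samples[0]
        rate = ts.streams["gsr"].rate_hz
        if method == "hrv_stat":
            n, h, s6 = cardio.gsr_features(x, rate)
            vals = np.concatenate([[n, h], s6])
            return vals, (["gsr_npeaks", "gsr_meanpeak"]
                          + [f"gsr_stat{i + 1}" for i in range(6)])
        if method == "spectro_deep":
            img = cardio.spectrogram_image(x, rate, f_max_hz=2.0)
            vec = embedder.embed(img.pixels)
            return vec, [f"gsr_spec_{i:04d}" for i in range(len(vec))]
    elif modality == "face":
        frames = ts.landmarks
        if method == "geometric":
            M = np.vstack([face_mod.geometric_features(f) for f in frames])
            block = face_mod.aggregate_trial(
                M, names=[s.feature_id for s in face_mod.FEATURE_SPECS],
                trial=trial)
            return block.values, list(block.names)
        if method == "deep_face":
            imgs = [resize_to_input(face_mod.render_face(f)) for f in frames]
            M = face_mod.face_embedding_sequence(imgs, embedder)
            block = face_mod.aggregate_trial(
                M, names=[f"vggf_{i:04d}" for i in range(M.shape[1])],
                trial=trial, method="deep_face")
            return block.values, list(block.names)
    raise ValueError(f"unsupported method {method!r} for modality {modality!r}")


def extract_trial_sequence(ts: TrialSlices, modality: str, embedder,
                           windows_per_second: float,
                           frame_stride: int = 6) -> np.ndarray:
    """Per-window feature sequence (steps x features) for the LSTM route."""
    if modality == "eeg":
        stream = eeg_mod.bandpass_eeg(ts.streams["eeg"])
        images = eeg_mod.topomap_sequence(stream, windows_per_second)
        return np.vstack([embedder.embed(img.pixels) for img in images])
    if modality == "face":
        frames = ts.landmarks[::frame_stride]
        return np.vstack([face_mod.geometric_features(f) for f in frames])
    raise ValueError(
        f"sequence features are defined for eeg/face only, not {modality!r}")


def extract_features(dataset: SyntheticDataset, config: PipelineConfig
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Feature matrix (trials x features) for all configured modalities."""
    embedder = get_embedder(config.embedder, seed=config.seed)
    rows, labels, subs = [], [], []
    names: list[str] | None = None
    for rec, ts in dataset.iter_trials(config.task):
        vecs, nm = [], []
        for m in config.modalities:
            v, n = extract_trial_features(
                ts, m, config.methods.get(m, DEFAULT_METHODS[m]), embedder)
            vecs.append(v)
            nm.extend(n)
        rows.append(np.concatenate(vecs))
        names = names or nm
        labels.append(_label_of(rec.trial, config.task))
        subs.append(rec.trial.subject_id)
    return np.vstack(rows), np.asarray(labels), np.asarray(subs), names


def extract_sequences(dataset: SyntheticDataset, config: PipelineConfig
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-length per-window sequences for every trial (LSTM route).

    Attention trials get one window per second; 2-s incident trials get 30
    windows per second (60 steps).
    """
    wps = 30.0 if config.task == "incident" else 1.0
    embedder = get_embedder(config.embedder, seed=config.seed)
    seqs, labels, subs = [], [], []
    for rec, ts in dataset.iter_trials(config.task):
        parts = [extract_trial_sequence(ts, m, embedder, wps,
                                        config.face_frame_stride)
                 for m in config.modalities]
        steps = min(p.shape[0] for p in parts)
        seqs.append(np.concatenate([p[:steps] for p in parts], axis=1))
        labels.append(_label_of(rec.trial, config.task))
        subs.append(rec.trial.subject_id)
    return np.stack(seqs), np.asarray(labels), np.asarray(subs)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Full run: synthesize (or reuse) data, extract, LOSO-evaluate, report."""
    if dataset is None:
        gen_cfg = GeneratorConfig(**{"seed": config.seed, **config.generator})
        dataset = gen_dataset(gen_cfg)
    if config.classifier == "lstm":
        X, y, subs = extract_sequences(dataset, config)
        clf = LSTMClassifier(random_state=config.seed, expected_input_dim=None)
        result = loso_cv(X, y, subs, classifier=clf, pca_k=min(
            config.seq_pca_k, X.shape[0] * X.shape[1] - 1, X.shape[2]),
            scaler_scope=config.scaler_scope, seed=config.seed)
        feature_df = None
    else:
        X, y, subs, names = extract_features(dataset, config)
        clf = ELMClassifier(n_hidden=config.n_hidden, random_state=config.seed)
        result = loso_cv(X, y, subs, classifier=clf,
                         pca_k=min(config.pca_k, X.shape[1], X.shape[0] - 1),
                         scaler_scope=config.scaler_scope, seed=config.seed)
        feature_df = pd.DataFrame(X, columns=names)
        feature_df.insert(0, "subject_id", subs)
        feature_df.insert(1, "label", y)
    report = {
        "config": config.to_dict(),
        "n_trials": int(len(y)),
        "n_subjects": int(len(np.unique(subs))),
        "metrics": result.summary(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if feature_df is not None:
            feature_df.to_csv(out / "features.csv", index=False,
                              float_format="%.17g")
        (out / "metrics.json").write_text(json.dumps(report, indent=2))
    return report
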