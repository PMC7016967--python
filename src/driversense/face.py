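"""Geometric facial-landmark features and per-trial aggregation.

Works on 49-point landmark layouts (brows 0-9, nose 10-18, eyes 19-30,
outer mouth 31-42, inner mouth 43-48).  Thirty geometric features are
computed per frame — 22 inter-landmark distances normalized by the face-box
dimensions (horizontal by width, vertical by height, oblique by the
diagonal) and 8 angles in radians (scale-free, so unnormalized) — then
summarized across the frames of a trial by mean, 95th percentile (more
robust than the maximum) and standard deviation, giving 90 values per trial.

The published landmark sets name only a few example measurements, so the
concrete 30-feature list below is this package's own reconstruction on the
standard 49-point layout; it preserves the stated structure (brow-eye,
nose-mouth and brow-brow distances, angles between such segments) and
left/right symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LandmarkFrame, Trial, FeatureBlock

# index groups on the canonical 49-point layout
LEFT_BROW = (0, 1, 2, 3, 4)
RIGHT_BROW = (5, 6, 7, 8, 9)
NOSE_BRIDGE_TOP = 10
NOSE_TIP = 16
NOSE_BOTTOM_L, NOSE_BOTTOM_R = 14, 18
LEFT_EYE = (19, 20, 21, 22, 23, 24)
RIGHT_EYE = (25, 26, 27, 28, 29, 30)
MOUTH_L, MOUTH_R = 31, 37
LIP_TOP_MID, LIP_BOT_MID = 34, 40
INNER_TOP_MID, INNER_BOT_MID = 44, 47


@dataclass(frozen=True)
class GeometricFeatureSpec:
    """One distance or angle on the 49-point layout.

    ``point_indices`` entries are landmark indices or tuples of indices
    (a tuple means the centroid of those points).  Distances carry a
    normalizer; angles are scale-free and use ``none``.
    """

    feature_id: str
    kind: str                     # {"distance", "angle"}
    point_indices: tuple
    normalizer: str               # {"face_w", "face_h", "diag", "none"}


_LBC = LEFT_BROW            # centroids written as tuples
_RBC = RIGHT_BROW
_LEC = LEFT_EYE
_REC = RIGHT_EYE
_LEH_T, _LEH_B = (20, 21), (23, 24)
_REH_T, _REH_B = (26, 27), (29, 30)
_BROW_MID = LEFT_BROW + RIGHT_BROW

#: The canonical 30-feature list: 22 distances + 8 angles.
FEATURE_SPECS: tuple[GeometricFeatureSpec, ...] = (
    GeometricFeatureSpec("geo01", "distance", (_LBC, _LEC), "face_h"),
    GeometricFeatureSpec("geo02", "distance", (_RBC, _REC), "face_h"),
    GeometricFeatureSpec("geo03", "distance", (_LBC, _RBC), "face_w"),
    GeometricFeatureSpec("geo04", "distance", (19, 22), "face_w"),
    GeometricFeatureSpec("geo05", "distance", (25, 28), "face_w"),
    GeometricFeatureSpec("geo06", "distance", (_LEH_T, _LEH_B), "face_h"),
    GeometricFeatureSpec("geo07", "distance", (_REH_T, _REH_B), "face_h"),
    GeometricFeatureSpec("geo08", "distance", (_LEC, _REC), "face_w"),
    GeometricFeatureSpec("geo09", "distance", (NOSE_TIP, MOUTH_L), "diag"),
    GeometricFeatureSpec("geo10", "distance", (NOSE_TIP, MOUTH_R), "diag"),
    GeometricFeatureSpec("geo11", "distance", (MOUTH_L, MOUTH_R), "face_w"),
    GeometricFeatureSpec("geo12", "distance", (LIP_TOP_MID, LIP_BOT_MID), "face_h"),
    GeometricFeatureSpec("geo13", "distance", (NOSE_BRIDGE_TOP, NOSE_TIP), "face_h"),
    GeometricFeatureSpec("geo14", "distance", (4, NOSE_BRIDGE_TOP), "diag"),
    GeometricFeatureSpec("geo15", "distance", (5, NOSE_BRIDGE_TOP), "diag"),
    GeometricFeatureSpec("geo16", "distance", (_BROW_MID, NOSE_TIP), "face_h"),
    GeometricFeatureSpec("geo17", "distance", (_LEC, MOUTH_L), "diag"),
    GeometricFeatureSpec("geo18", "distance", (_REC, MOUTH_R), "diag"),
    GeometricFeatureSpec("geo19", "distance", (NOSE_BOTTOM_L, NOSE_BOTTOM_R), "face_w"),
    GeometricFeatureSpec("geo20", "distance", (INNER_TOP_MID, INNER_BOT_MID), "face_h"),
    GeometricFeatureSpec("geo21", "distance", (LIP_TOP_MID, NOSE_TIP), "face_h"),
    GeometricFeatureSpec("geo22", "distance", (LIP_BOT_MID, NOSE_TIP), "face_h"),
    GeometricFeatureSpec("geo23", "angle", (MOUTH_L, LIP_TOP_MID, LIP_BOT_MID), "none"),
    GeometricFeatureSpec("geo24", "angle", (MOUTH_R, LIP_TOP_MID, LIP_BOT_MID), "none"),
    GeometricFeatureSpec("geo25", "angle", (NOSE_TIP, MOUTH_L, MOUTH_R), "none"),
    GeometricFeatureSpec("geo26", "angle", (_LEC, _LBC, NOSE_TIP), "none"),
    GeometricFeatureSpec("geo27", "angle", (_REC, _RBC, NOSE_TIP), "none"),
    GeometricFeatureSpec("geo28", "angle", (_BROW_MID, _LEC, _REC), "none"),
    GeometricFeatureSpec("geo29", "angle", (LIP_TOP_MID, MOUTH_L, MOUTH_R), "none"),
    GeometricFeatureSpec("geo30", "angle", (LIP_BOT_MID, MOUTH_L, MOUTH_R), "none"),
)

#: 1-based id pairs that are left/right mirror images of each other.
SYMMETRIC_PAIRS = ((1, 2), (4, 5), (6, 7), (9, 10), (14, 15), (17, 18),
                   (23, 24), (26, 27))


def _resolve(points: np.ndarray, ref) -> np.ndarray:
    if isinstance(ref, tuple):
        return points[list(ref)].mean(axis=0)
    return points[ref]


def geometric_features(frame: LandmarkFrame,
                       specs: Sequence[GeometricFeatureSpec] = FEATURE_SPECS,
                       ) -> np.ndarray:
    """Evaluate the canonical geometric feature list on one landmark frame.

    Distances are normalized by the face box (width/height/diagonal), making
    them invariant to camera distance; angles are returned in radians.  A
    degenerate angle (coincident points) yields 0 with a warning.
    """
    import warnings

    pts = frame.points
    diag = float(np.hypot(frame.face_w, frame.face_h))
    norms = {"face_w": frame.face_w, "face_h": frame.face_h,
             "diag": diag, "none": 1.0}
    out = np.empty(len(specs))
    for i, spec in enumerate(specs):
        if spec.kind == "distance":
            a, b = (_resolve(pts, r) for r in spec.point_indices)
            out[i] = np.linalg.norm(a - b) / norms[spec.normalizer]
        else:                                    # angle at vertex v between a, b
            v, a, b = (_resolve(pts, r) for r in spec.point_indices)
            u1, u2 = a - v, b - v
            n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
            if n1 == 0 or n2 == 0:
                warnings.warn(f"{spec.feature_id}: degenerate angle "
                              "(coincident points); feature set to 0",
                              RuntimeWarning, stacklevel=2)
                out[i] = 0.0
            else:
                out[i] = np.arccos(np.clip(u1 @ u2 / (n1 * n2), -1.0, 1.0))
    return out


@dataclass
class TrialAggregate:
    """Columnwise mean / 95th percentile / standard deviation across frames."""

    mean_vec: np.ndarray
    p95_vec: np.ndarray
    std_vec: np.ndarray


def aggregate_trial(framewise: np.ndarray,
                    names: Sequence[str] | None = None,
                    trial: Trial | None = None,
                    modality: str = "face",
                    method: str = "geometric") -> FeatureBlock:
    """Summarize a (frames x features) matrix into mean/p95/std per column.

    30 geometric columns become a 90-value block; a 4096-wide embedding
    matrix becomes 12288 values.  The 95th percentile uses the
    linear-interpolation quantile definition; std uses the n-1 (sample)
    denominator, hence the two-frame minimum.
    """
    M = np.asarray(framewise, dtype=float)
    if M.ndim != 2:
        raise ValueError("framewise matrix must be 2-D (frames x features)")
    if M.shape[0] < 2:
        raise ValueError("trial aggregation needs at least 2 frames "
                         "(std is undefined on one)")
    agg = TrialAggregate(
        mean_vec=M.mean(axis=0),
        p95_vec=np.percentile(M, 95, axis=0, method="linear"),
        std_vec=M.std(axis=0, ddof=1),
    )
    if names is None:
        width = len(str(M.shape[1]))
        names = [f"col{j + 1:0{width}d}" for j in range(M.shape[1])]
    full_names = ([f"{n}_mean" for n in names]
                  + [f"{n}_p95" for n in names]
                  + [f"{n}_std" for n in names])
    values = np.concatenate([agg.mean_vec, agg.p95_vec, agg.std_vec])
    ref = trial if trial is not None else Trial("?", "synthetic", 0.0, 1.0)
    return FeatureBlock(ref, modality, method, values, tuple(full_names))


def face_embedding_sequence(face_images: Sequence[np.ndarray],
                            embedder) -> np.ndarray:
    """Embed each face frame; returns a (frames x 4096) matrix, order kept."""
    rows = []
    for img in face_images:
        v = np.asarray(embedder.embed(img)).ravel()
        if len(v) != embedder.output_dim:
            raise ValueError(
                f"embedder returned {len(v)} values, expected "
                f"{embedder.output_dim}")
        rows.append(v)
    return np.vstack(rows)


def render_face(frame: LandmarkFrame, size: int = 224,
                sigma_px: float = 2.0) -> np.ndarray:
    """Rasterize a landmark frame into a synthetic grayscale-RGB face image.

    A deterministic stand-in for real camera crops: each landmark becomes a
    Gaussian blob on a dark canvas, scaled so the face box fills the image.
    Exists so the deep-face route can run end-to-end on synthetic data.
    """
    canvas = np.zeros((size, size))
    pts = frame.points.copy()
    lo = pts.min(axis=0)
    span = np.array([frame.face_w, frame.face_h], dtype=float)
    scaled = (pts - lo) / span * (size * 0.8) + size * 0.1
    ys, xs = np.mgrid[0:size, 0:size]
    for x, y in scaled:
        canvas += np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma_px ** 2))
    canvas = canvas / canvas.max() if canvas.max() > 0 else canvas
    return np.repeat(canvas[:, :, None], 3, axis=2)
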