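"""Hand-skeleton kinematic features: joint angles and fingertip-palm distances.

Per frame, 19 features in fixed order: 14 interior joint angles (thumb T1-T2,
then I1-I3, M1-M3, R1-R3, P1-P3, degrees) and 5 fingertip-to-palm-center
Euclidean distances (D1-D5, thumb to little, mm).  A fully open hand attains
the angle maximum of 180 deg at every joint.  Frames are cropped to the
middle of the hold, windowed with the shared sliding-window configuration
(5 frames per 250 ms window at 20 fps) and averaged per window so kinematic
rows align one-to-one with EMG feature rows.
"""

from __future__ import annotations

import numpy as np

from .data import (
    FINGERS,
    KIN_FEATURE_NAMES,
    FeatureMatrix,
    HandFrame,
    HandFrameSequence,
    WindowingConfig,
)

def joint_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle (degrees, in [0, 180]) between two bone vectors meeting at a joint.

    u points from the joint toward the far end of the proximal bone, v from
    the joint toward the far end of the distal bone, so a straight finger
    gives 180 deg.  Evaluated as atan2(|u x v|, u.v) — identical to
    arccos of the clamped normalized dot product but well-conditioned near
    0 and 180 deg, so near-(anti)parallel vectors never produce NaN and the
    extremes are attained exactly.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("joint_angle requires nonzero bone vectors")
    cross = np.cross(u, v)
    return float(np.degrees(np.arctan2(np.linalg.norm(cross), np.dot(u, v))))


def fingertip_palm_distance(p: np.ndarray, o: np.ndarray) -> float:
    """Euclidean distance (mm) between a fingertip P and the palm center O."""
    p = np.asarray(p, dtype=float)
    o = np.asarray(o, dtype=float)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(o))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - o))


def _chain_angles(chain: np.ndarray) -> np.ndarray:
    """Interior joint angles of one chain; chain is (..., n_points, 3)."""
    bones = np.diff(chain, axis=-2)                     # (..., n_bones, 3)
    norms = np.linalg.norm(bones, axis=-1)
    if np.any(norms == 0.0):
        raise ValueError("degenerate chain: coincident consecutive joints")
    u = -bones[..., :-1, :]                             # joint -> proximal end
    v = bones[..., 1:, :]                               # joint -> distal end
    dot = np.sum(u * v, axis=-1)
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def frame_features(frame: HandFrame) -> np.ndarray:
    """The 19-dim kinematic feature vector of one hand frame."""
    angles = [
        _chain_angles(frame.fingers[name]) for name in FINGERS
    ]
    dists = [
        fingertip_palm_distance(frame.fingertip(name), frame.palm_center)
        for name in FINGERS
    ]
    out = np.concatenate(angles + [np.asarray(dists)])
    assert out.shape == (19,)
    return out


def sequence_features(seq: HandFrameSequence) -> np.ndarray:
    """Per-frame 19-dim features for a whole sequence, shape (n_frames, 19)."""
    angle_blocks = [_chain_angles(seq.fingers[name]) for name in FINGERS]
    tips = np.stack([seq.fingers[name][:, -1, :] for name in FINGERS], axis=1)
    dists = np.linalg.norm(tips - seq.palm[:, None, :], axis=-1)
    return np.concatenate(angle_blocks + [dists], axis=1)


def crop_middle_frames(seq: HandFrameSequence, span_s: float) -> HandFrameSequence:
    """Centered crop of a frame sequence, same rule as the EMG crop."""
    n_span = int(round(span_s * seq.fps))
    if n_span > len(seq):
        raise ValueError(
            f"sequence of {len(seq)} frames shorter than requested span "
            f"{span_s} s ({n_span} frames)"
        )
    start = (len(seq) - n_span) // 2
    return seq.slice(start, start + n_span)


def extract_kin_features(
    frames: HandFrameSequence,
    cfg: WindowingConfig = WindowingConfig(),
    label: str | None = None,
    subject: str = "",
    trial: str = "",
) -> FeatureMatrix:
    """Windowed kinematic features for one trial.

    Crops the middle ``cfg.analysis_span_s`` seconds, slides a window of
    ``cfg.window_ms`` stepping by ``cfg.step_ms`` over the frames and
    averages the per-frame 19-vectors within each window.  The window count
    matches the EMG extractor's for the same configuration.
    """
    cropped = crop_middle_frames(frames, cfg.analysis_span_s)
    per_frame = sequence_features(cropped)
    w = cfg.window_samples(frames.fps)
    s = cfg.step_samples(frames.fps)
    n = per_frame.shape[0]
    if w < 1 or w > n:
        raise ValueError(
            f"window of {w} frames does not fit in {n} cropped frames"
        )
    n_win = (n - w) // s + 1
    rows = np.stack(
        [per_frame[i * s:i * s + w].mean(axis=0) for i in range(n_win)]
    )
    lab = "" if label is None else label
    return FeatureMatrix(
        X=rows,
        labels=np.array([lab] * n_win),
        subjects=np.array([subject] * n_win),
        trials=np.array([trial] * n_win),
        columns=KIN_FEATURE_NAMES,
    )
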