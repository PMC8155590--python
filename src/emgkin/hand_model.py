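"""Planar-chain hand skeleton used to realize poses from joint angles.

Each finger is a chain of rigid bones confined to its own plane, spanned by
the finger's abduction direction in the palm plane and the palm normal.
An interior joint angle of 180 deg means the two adjacent bones are
collinear (finger fully extended, the maximum of the angle range); smaller
angles curl the finger toward the palm.  Bone lengths are fixed
anthropometric constants in millimetres.

The 14-angle layout follows the feature order T1,T2 (thumb, which has no
metacarpal and hence two interior joints), then I1-I3, M1-M3, R1-R3, P1-P3
for the four three-joint fingers.
"""

from __future__ import annotations

import numpy as np

from .data import FINGERS, HandFrame, HandFrameSequence

#: Bone lengths (mm), base -> tip.  Thumb: proximal, intermediate, distal.
#: Other fingers: metacarpal, proximal, intermediate, distal.
BONE_LENGTHS_MM: dict[str, tuple[float, ...]] = {
    "thumb": (46.0, 32.0, 30.0),
    "index": (68.0, 43.0, 25.0, 23.0),
    "middle": (64.0, 48.0, 28.0, 24.0),
    "ring": (58.0, 44.0, 27.0, 24.0),
    "little": (54.0, 33.0, 20.0, 21.0),
}

#: Chain base point relative to the palm center (mm).  Non-thumb metacarpals
#: emanate from the palm center; the thumb column starts on the radial edge.
BASE_OFFSETS_MM: dict[str, tuple[float, float, float]] = {
    "thumb": (-28.0, -12.0, 0.0),
    "index": (0.0, 0.0, 0.0),
    "middle": (0.0, 0.0, 0.0),
    "ring": (0.0, 0.0, 0.0),
    "little": (0.0, 0.0, 0.0),
}

#: In-palm-plane pointing direction of each straight finger (unit vectors).
_DIRECTIONS: dict[str, np.ndarray] = {
    "thumb": np.array([-0.80, 0.60, 0.0]),
    "index": np.array([-0.20, 0.9798, 0.0]),
    "middle": np.array([0.0, 1.0, 0.0]),
    "ring": np.array([0.20, 0.9798, 0.0]),
    "little": np.array([0.38, 0.925, 0.0]),
}
FINGER_DIRECTIONS: dict[str, np.ndarray] = {
    k: v / np.linalg.norm(v) for k, v in _DIRECTIONS.items()
}

#: Number of interior joint angles per finger, in FINGERS order (2+3*4 = 14).
ANGLES_PER_FINGER: dict[str, int] = {
    "thumb": 2, "index": 3, "middle": 3, "ring": 3, "little": 3,
}

_PALM_NORMAL = np.array([0.0, 0.0, 1.0])  # flexion curls toward -z


def split_angles(angles14: np.ndarray) -> dict[str, np.ndarray]:
    """Split the flat 14-angle vector into per-finger blocks (T, I, M, R, P)."""
    angles14 = np.asarray(angles14, dtype=float)
    if angles14.shape[-1] != 14:
        raise ValueError(f"expected 14 joint angles, got {angles14.shape[-1]}")
    out: dict[str, np.ndarray] = {}
    i = 0
    for name in FINGERS:
        k = ANGLES_PER_FINGER[name]
        out[name] = angles14[..., i:i + k]
        i += k
    return out


def chain_points(finger: str, joint_angles_deg: np.ndarray) -> np.ndarray:
    """Realize one finger chain from its interior joint angles.

    joint_angles_deg may be (k,) for a single pose or (n, k) for n poses;
    returns (n_points, 3) or (n, n_points, 3) respectively.  The first bone
    lies along the finger direction in the palm plane; each interior joint
    with angle theta turns the chain by 180 - theta deg toward the palm
    normal's negative side, so theta = 180 keeps the chain straight.
    """
    ang = np.atleast_2d(np.asarray(joint_angles_deg, dtype=float))
    lengths = np.asarray(BONE_LENGTHS_MM[finger])
    n_bones = lengths.shape[0]
    if ang.shape[1] != n_bones - 1:
        raise ValueError(
            f"{finger} expects {n_bones - 1} joint angles, got {ang.shape[1]}"
        )
    turns = np.deg2rad(180.0 - ang)                      # (n, n_bones-1)
    phi = np.concatenate(
        [np.zeros((ang.shape[0], 1)), np.cumsum(turns, axis=1)], axis=1
    )                                                    # (n, n_bones)
    d = FINGER_DIRECTIONS[finger]
    # direction of bone j: cos(phi) * d - sin(phi) * z  (curl toward -z)
    dirs = (
        np.cos(phi)[..., None] * d[None, None, :]
        - np.sin(phi)[..., None] * _PALM_NORMAL[None, None, :]
    )                                                    # (n, n_bones, 3)
    bones = dirs * lengths[None, :, None]
    base = np.asarray(BASE_OFFSETS_MM[finger])
    pts = np.concatenate(
        [np.broadcast_to(base, (ang.shape[0], 1, 3)),
         base + np.cumsum(bones, axis=1)], axis=1
    )                                                    # (n, n_bones+1, 3)
    if np.asarray(joint_angles_deg).ndim == 1:
        return pts[0]
    return pts


def pose_from_angles(angles14: np.ndarray) -> HandFrame:
    """Build a single HandFrame (palm at the origin) from 14 joint angles."""
    per_finger = split_angles(np.asarray(angles14, dtype=float).reshape(14))
    return HandFrame(
        palm_center=np.zeros(3),
        fingers={f: chain_points(f, a) for f, a in per_finger.items()},
    )


def poses_from_angles(angles14: np.ndarray, fps: float,
                      times: np.ndarray | None = None) -> HandFrameSequence:
    """Build a HandFrameSequence from an (n_frames, 14) angle array."""
    angles14 = np.asarray(angles14, dtype=float)
    if angles14.ndim != 2 or angles14.shape[1] != 14:
        raise ValueError("expected an (n_frames, 14) angle array")
    n = angles14.shape[0]
    per_finger = split_angles(angles14)
    if times is None:
        times = np.arange(n) / fps
    return HandFrameSequence(
        times=times,
        palm=np.zeros((n, 3)),
        fingers={f: chain_points(f, a) for f, a in per_finger.items()},
        fps=fps,
    )
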