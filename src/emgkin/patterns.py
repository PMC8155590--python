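"""Pattern templates and subject profiles for the synthetic cohort.

A PatternTemplate fixes, for one of the eight hand patterns, (a) the mean
activation amplitude of the four recorded muscles and (b) the hand pose as
14 target joint angles; the five fingertip-palm target distances follow
deterministically from the angles through the planar-chain skeleton, so the
angle/distance pair always round-trips exactly through feature extraction.

The default templates encode two deliberate, physiologically motivated
confusions: finger_close is kinematically close to hand_open (near-straight
fingers) but has a distinct muscle-activation signature, while
cylindrical_grip has EMG amplitudes close to fist but a clearly different
pose.  Each modality alone therefore has a hard pair, and fusing the two
resolves both — the structure the fusion experiment probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import PATTERNS
from .hand_model import pose_from_angles
from .kinematics import frame_features

# per-finger interior angles (deg): thumb (2,), then index/middle/ring/little (3,)
_TEMPLATE_ANGLES: dict[str, tuple[tuple[float, ...], ...]] = {
    "finger_bend": ((150, 145), (150, 130, 140), (150, 130, 140), (150, 130, 140), (150, 130, 140)),
    "finger_close": ((172, 176), (176, 179, 179), (176, 179, 179), (176, 179, 179), (176, 179, 179)),
    "finger_flexion": ((150, 170), (100, 175, 175), (100, 175, 175), (100, 175, 175), (100, 175, 175)),
    "hand_open": ((180, 180), (180, 180, 180), (180, 180, 180), (180, 180, 180), (180, 180, 180)),
    "lateral_pinch": ((125, 135), (140, 120, 130), (110, 90, 100), (110, 90, 100), (110, 90, 100)),
    "fingertip_to_fingertip": ((140, 140), (130, 110, 120), (130, 110, 120), (130, 110, 120), (130, 110, 120)),
    "fist": ((115, 105), (100, 80, 90), (100, 80, 90), (100, 80, 90), (100, 80, 90)),
    "cylindrical_grip": ((138, 128), (132, 112, 118), (132, 112, 118), (132, 112, 118), (132, 112, 118)),
}

# mean activation envelope per muscle (APB, FCR, ED, ECU), volt-scale units
_TEMPLATE_ACTIVATIONS: dict[str, tuple[float, float, float, float]] = {
    "finger_bend": (1.2e-5, 1.8e-5, 2.5e-5, 1.5e-5),
    "finger_close": (0.8e-5, 1.0e-5, 3.0e-5, 2.0e-5),
    "finger_flexion": (1.0e-5, 2.8e-5, 1.2e-5, 1.8e-5),
    "hand_open": (0.9e-5, 0.7e-5, 3.5e-5, 2.6e-5),
    "lateral_pinch": (3.2e-5, 1.5e-5, 1.0e-5, 1.2e-5),
    "fingertip_to_fingertip": (2.8e-5, 2.0e-5, 1.6e-5, 1.0e-5),
    "fist": (1.8e-5, 3.5e-5, 1.4e-5, 2.4e-5),
    "cylindrical_grip": (1.9e-5, 3.3e-5, 1.5e-5, 2.5e-5),
}


@dataclass(frozen=True)
class PatternTemplate:
    """Target activation amplitudes and hand pose for one pattern."""

    pattern_id: str
    muscle_activation: np.ndarray   # (4,) nonnegative, signal units
    target_angles: np.ndarray       # (14,) degrees in [0, 180]
    target_distances: np.ndarray    # (5,) mm, nonnegative

    def __post_init__(self) -> None:
        if self.pattern_id not in PATTERNS:
            raise ValueError(f"unknown pattern: {self.pattern_id!r}")
        act = np.asarray(self.muscle_activation, dtype=float).reshape(4)
        ang = np.asarray(self.target_angles, dtype=float).reshape(14)
        dist = np.asarray(self.target_distances, dtype=float).reshape(5)
        if np.any(act < 0):
            raise ValueError("activation amplitudes must be nonnegative")
        if np.any(ang < 0) or np.any(ang > 180):
            raise ValueError("joint angles must lie in [0, 180] degrees")
        if np.any(dist < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "muscle_activation", act)
        object.__setattr__(self, "target_angles", ang)
        object.__setattr__(self, "target_distances", dist)

    @property
    def kinematic_signature(self) -> np.ndarray:
        """The 19-dim (angles, distances) vector of the noise-free pose."""
        return np.concatenate([self.target_angles, self.target_distances])


def template_from_angles(
    pattern_id: str,
    angles14: np.ndarray,
    muscle_activation: np.ndarray,
) -> PatternTemplate:
    """Build a template whose distances are measured off the realized pose."""
    feats = frame_features(pose_from_angles(angles14))
    return PatternTemplate(
        pattern_id=pattern_id,
        muscle_activation=np.asarray(muscle_activation, dtype=float),
        target_angles=np.asarray(angles14, dtype=float),
        target_distances=feats[14:],
    )


def make_default_templates() -> dict[str, PatternTemplate]:
    """The eight default pattern templates, keyed by pattern id.

    hand_open has every joint at the 180-deg maximum and hence the maximal
    fingertip-palm distances; fist is the most flexed pose.  All eight are
    pairwise distinct in their 19-dim kinematic signature.
    """
    out: dict[str, PatternTemplate] = {}
    for pid in PATTERNS:
        flat = np.concatenate([np.asarray(b, dtype=float)
                               for b in _TEMPLATE_ANGLES[pid]])
        out[pid] = template_from_angles(pid, flat, _TEMPLATE_ACTIVATIONS[pid])
    return out


@dataclass(frozen=True)
class SubjectProfile:
    """Signal-quality parameters of one virtual subject.

    kinematic_jitter_deg is the per-frame angle noise sd; pose_drift_deg a
    per-trial constant angle offset sd (trial-to-trial pose variability);
    amplitude_jitter the sd of the per-trial lognormal EMG amplitude factor.
    Post-stroke profiles attenuate activation amplitudes and are noisier on
    both modalities.
    """

    subject_id: str
    group: str = "normal"            # "normal" | "post_stroke"
    n_reps: int = 10
    emg_noise_floor: float = 2e-6
    kinematic_jitter_deg: float = 3.0
    pose_drift_deg: float = 2.0
    amplitude_jitter: float = 0.2
    activation_attenuation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("normal", "post_stroke"):
            raise ValueError(f"unknown group: {self.group!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.emg_noise_floor < 0 or self.kinematic_jitter_deg < 0 \
                or self.pose_drift_deg < 0 or self.amplitude_jitter < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0 < self.activation_attenuation <= 1:
            raise ValueError("activation_attenuation must lie in (0, 1]")


def normal_profile(subject_id: str, seed: int) -> SubjectProfile:
    """Default unimpaired subject: 10 repetitions per pattern."""
    return SubjectProfile(subject_id=subject_id, group="normal", n_reps=10,
                          seed=seed)


def stroke_profile(subject_id: str, seed: int) -> SubjectProfile:
    """Default post-stroke subject: 5 repetitions, attenuated and noisier.

    Attenuation pushes the activation vectors toward the noise floor and
    toward each other (lower EMG separability); larger pose jitter and drift
    emulate impaired, less repeatable hand postures.
    """
    return SubjectProfile(
        subject_id=subject_id,
        group="post_stroke",
        n_reps=5,
        emg_noise_floor=4e-6,
        kinematic_jitter_deg=6.0,
        pose_drift_deg=4.0,
        amplitude_jitter=0.35,
        activation_attenuation=0.6,
        seed=seed,
    )
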