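"""Synthetic synchronized EMG + hand-kinematics trial generator.

The generator emulates the statistical structure of the recording protocol
the downstream pipeline expects: eight static hand patterns held for 5 s,
four surface-EMG channels at 2000 Hz with per-pattern activation amplitude
profiles of order 1e-5 signal units, and a 20 fps hand-skeleton stream whose
recomputed joint angles scatter around the pattern's target pose.

EMG is modelled as amplitude-modulated band-limited (20-450 Hz) Gaussian
noise per channel — the standard surrogate for surface EMG interference
signals — which makes window statistics analytically checkable (for a
Gaussian envelope sigma, E|x| = sigma * sqrt(2/pi)).  Every generator is a
pure function of its arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal

from .data import MUSCLES, PATTERNS, EMGRecording, HandFrameSequence, Trial
from .hand_model import poses_from_angles
from .patterns import (
    PatternTemplate,
    SubjectProfile,
    make_default_templates,
    normal_profile,
    stroke_profile,
)

#: Synthesis band of the EMG carrier (Hz); within the 20-500 Hz analysis band.
EMG_BAND_HZ: tuple[float, float] = (20.0, 450.0)


def _carrier_sos(fs: float) -> np.ndarray:
    low, high = EMG_BAND_HZ
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def simulate_emg(
    template: PatternTemplate,
    profile: SubjectProfile,
    duration_s: float = 5.0,
    fs: float = 2000.0,
    seed: int = 0,
) -> EMGRecording:
    """Simulate one 4-channel EMG hold for a pattern/subject combination.

    Each channel is band-limited Gaussian noise normalized to unit sample
    standard deviation and scaled to an envelope of
    ``activation * attenuation * trial_factor``, where the trial factor is a
    lognormal effort fluctuation shared across channels, plus a white
    Gaussian sensor noise floor.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if fs <= 2 * EMG_BAND_HZ[1]:
        raise ValueError(f"fs must exceed twice the synthesis band edge "
                         f"({EMG_BAND_HZ[1]} Hz)")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    trial_factor = float(np.exp(rng.normal(0.0, profile.amplitude_jitter)))
    sos = _carrier_sos(fs)
    out = np.empty((4, n))
    for c in range(4):
        carrier = signal.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= carrier.std()
        sigma = (template.muscle_activation[c]
                 * profile.activation_attenuation * trial_factor)
        out[c] = sigma * carrier + profile.emg_noise_floor * rng.standard_normal(n)
    return EMGRecording(samples=out, fs=fs, channel_names=MUSCLES)


def simulate_kinematics(
    template: PatternTemplate,
    profile: SubjectProfile,
    duration_s: float = 5.0,
    fps: float = 20.0,
    seed: int = 0,
) -> HandFrameSequence:
    """Simulate one hand-skeleton frame sequence holding a pattern's pose.

    Realized per-frame joint angles are ``target + trial drift + frame
    noise`` with drift sd ``pose_drift_deg`` (constant within the trial) and
    frame noise sd ``kinematic_jitter_deg``; the planar-chain skeleton turns
    them into 3-D joint positions, so re-extracting angles recovers exactly
    the noisy targets (folded into [0, 180] where noise crosses a bound).
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    n = int(round(duration_s * fps))
    rng = np.random.default_rng(seed)
    drift = rng.normal(0.0, profile.pose_drift_deg, 14)
    noise = rng.normal(0.0, profile.kinematic_jitter_deg, (n, 14))
    angles = template.target_angles[None, :] + drift[None, :] + noise
    return poses_from_angles(angles, fps=fps)


def _resolve_templates(
    templates: Mapping[str, PatternTemplate] | Iterable[PatternTemplate] | None,
) -> dict[str, PatternTemplate]:
    if templates is None:
        return make_default_templates()
    if isinstance(templates, Mapping):
        tdict = dict(templates)
    else:
        tdict = {t.pattern_id: t for t in templates}
    missing = [p for p in PATTERNS if p not in tdict]
    if missing:
        raise ValueError(f"missing template(s) for pattern(s): {missing}")
    extra = [p for p in tdict if p not in PATTERNS]
    if extra:
        raise ValueError(f"unknown pattern id(s) in templates: {extra}")
    return tdict


def _trial_seeds(profile_seed: int, pattern_index: int, rep: int) -> tuple[int, int]:
    ss = np.random.SeedSequence([profile_seed, pattern_index, rep])
    a, b = ss.generate_state(2)
    return int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF


@dataclass(frozen=True)
class Cohort:
    """A list of labeled trials plus the subject profiles that produced them."""

    profiles: tuple[SubjectProfile, ...]
    trials: tuple[Trial, ...]

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(p.subject_id for p in self.profiles)

    def group_of(self, subject_id: str) -> str:
        for p in self.profiles:
            if p.subject_id == subject_id:
                return p.group
        raise KeyError(subject_id)

    def trials_of(self, subject_id: str) -> list[Trial]:
        return [t for t in self.trials if t.subject_id == subject_id]


def simulate_cohort(
    profiles: Sequence[SubjectProfile],
    templates: Mapping[str, PatternTemplate] | Iterable[PatternTemplate] | None = None,
    duration_s: float = 5.0,
    fs: float = 2000.0,
    fps: float = 20.0,
) -> Cohort:
    """Simulate every subject's ``n_reps`` repetitions of all 8 patterns.

    Per-trial seeds are derived deterministically from each profile's seed,
    so identical profiles yield an identical cohort.
    """
    if len(profiles) == 0:
        raise ValueError("profiles must be nonempty")
    tdict = _resolve_templates(templates)
    trials: list[Trial] = []
    for profile in profiles:
        for p_idx, pattern in enumerate(PATTERNS):
            template = tdict[pattern]
            for rep in range(profile.n_reps):
                emg_seed, kin_seed = _trial_seeds(profile.seed, p_idx, rep)
                emg = simulate_emg(template, profile, duration_s, fs, emg_seed)
                frames = simulate_kinematics(template, profile, duration_s,
                                             fps, kin_seed)
                trials.append(Trial(
                    label=pattern,
                    emg=emg,
                    frames=frames,
                    subject_id=profile.subject_id,
                    group=profile.group,
                    rep=rep,
                    trial_id=f"{profile.subject_id}:{pattern}:{rep}",
                ))
    return Cohort(profiles=tuple(profiles), trials=tuple(trials))


def default_profiles(
    n_normal: int = 10,
    n_stroke: int = 5,
    seed: int = 0,
) -> list[SubjectProfile]:
    """The default virtual cohort: 10 normal + 5 post-stroke subjects."""
    profiles: list[SubjectProfile] = []
    for i in range(n_normal):
        s = int(np.random.SeedSequence([seed, 0, i]).generate_state(1)[0]) & 0x7FFFFFFF
        profiles.append(normal_profile(f"N{i + 1:02d}", seed=s))
    for i in range(n_stroke):
        s = int(np.random.SeedSequence([seed, 1, i]).generate_state(1)[0]) & 0x7FFFFFFF
        profiles.append(stroke_profile(f"P{i + 1:02d}", seed=s))
    return profiles


def default_cohort(n_normal: int = 10, n_stroke: int = 5, seed: int = 0) -> Cohort:
    """Simulate the default cohort with all defaults (one call convenience)."""
    return simulate_cohort(default_profiles(n_normal, n_stroke, seed))
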