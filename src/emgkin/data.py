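"""Shared data containers for multimodal (EMG + hand kinematics) trials.

Containers are deliberately thin: numpy arrays with validated metadata.
All positions are in millimetres, angles in degrees, EMG in volt-scale
arbitrary units (typical surface-EMG magnitudes of order 1e-5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The eight static hand patterns of daily living, in canonical order.
PATTERNS: tuple[str, ...] = (
    "finger_bend",
    "finger_close",
    "finger_flexion",
    "hand_open",
    "lateral_pinch",
    "fingertip_to_fingertip",
    "fist",
    "cylindrical_grip",
)

#: Recording sites, channel order ch1..ch4.
MUSCLES: tuple[str, ...] = (
    "abductor pollicis brevis",
    "flexor carpi radialis",
    "extensor digitorum",
    "extensor carpi ulnaris",
)

#: Finger order used everywhere (feature order T, I, M, R, P).
FINGERS: tuple[str, ...] = ("thumb", "index", "middle", "ring", "little")

#: Names of the 19 kinematic features in their fixed order.
KIN_FEATURE_NAMES: tuple[str, ...] = (
    "T1", "T2",
    "I1", "I2", "I3",
    "M1", "M2", "M3",
    "R1", "R2", "R3",
    "P1", "P2", "P3",
    "D1", "D2", "D3", "D4", "D5",
)

#: Time-domain EMG feature order within each channel block.
TD_FEATURE_NAMES: tuple[str, ...] = ("MAV", "ZC", "SSC", "DAMV", "VAR")


@dataclass(frozen=True)
class EMGRecording:
    """Multichannel raw (or filtered) surface EMG.

    samples has shape (n_channels, n_samples); fs is the sampling rate in Hz.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = MUSCLES

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 2 or samples.shape[0] < 1:
            raise ValueError("samples must be a (channels, time) matrix with >=1 channel")
        if not np.all(np.isfinite(samples)):
            raise ValueError("EMG samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray) -> "EMGRecording":
        return replace(self, samples=samples)


@dataclass(frozen=True)
class HandFrame:
    """One hand-skeleton snapshot: palm center plus five finger joint chains.

    Each chain is an (n_points, 3) array ordered base -> fingertip; the thumb
    has 4 points (3 bones, no metacarpal), every other finger 5 points
    (4 bones).  Interior points are the joints at which angles are measured.
    """

    palm_center: np.ndarray
    fingers: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        palm = np.asarray(self.palm_center, dtype=float).reshape(3)
        if not np.all(np.isfinite(palm)):
            raise ValueError("palm center must be finite")
        chains: dict[str, np.ndarray] = {}
        for name in FINGERS:
            if name not in self.fingers:
                raise ValueError(f"missing finger chain: {name}")
            chain = np.asarray(self.fingers[name], dtype=float)
            expected = 4 if name == "thumb" else 5
            if chain.shape != (expected, 3):
                raise ValueError(
                    f"{name} chain must have shape ({expected}, 3), got {chain.shape}"
                )
            if not np.all(np.isfinite(chain)):
                raise ValueError(f"{name} chain has non-finite coordinates")
            if np.any(np.linalg.norm(np.diff(chain, axis=0), axis=1) == 0):
                raise ValueError(f"{name} chain has coincident consecutive points")
            chains[name] = chain
        object.__setattr__(self, "palm_center", palm)
        object.__setattr__(self, "fingers", chains)

    def fingertip(self, finger: str) -> np.ndarray:
        return self.fingers[finger][-1]


@dataclass(frozen=True)
class HandFrameSequence:
    """Timestamped sequence of hand frames stored as stacked arrays.

    palm has shape (n_frames, 3); fingers maps finger name to
    (n_frames, n_points, 3).
    """

    times: np.ndarray
    palm: np.ndarray
    fingers: dict[str, np.ndarray]
    fps: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        palm = np.asarray(self.palm, dtype=float)
        n = times.shape[0]
        if palm.shape != (n, 3):
            raise ValueError("palm must have shape (n_frames, 3)")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        stacked: dict[str, np.ndarray] = {}
        for name in FINGERS:
            chain = np.asarray(self.fingers[name], dtype=float)
            expected = 4 if name == "thumb" else 5
            if chain.shape != (n, expected, 3):
                raise ValueError(f"{name} must have shape (n, {expected}, 3)")
            stacked[name] = chain
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "palm", palm)
        object.__setattr__(self, "fingers", stacked)

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def duration_s(self) -> float:
        return len(self) / self.fps

    def frame(self, i: int) -> HandFrame:
        return HandFrame(
            palm_center=self.palm[i],
            fingers={name: chain[i] for name, chain in self.fingers.items()},
        )

    def slice(self, start: int, stop: int) -> "HandFrameSequence":
        return HandFrameSequence(
            times=self.times[start:stop],
            palm=self.palm[start:stop],
            fingers={k: v[start:stop] for k, v in self.fingers.items()},
            fps=self.fps,
        )


@dataclass(frozen=True)
class Trial:
    """One labeled 5-s hold: synchronized EMG and hand-frame sequence."""

    label: str
    emg: EMGRecording
    frames: HandFrameSequence
    subject_id: str = ""
    group: str = ""
    rep: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in PATTERNS:
            raise ValueError(f"unknown pattern label: {self.label!r}")
        if abs(self.emg.duration_s - self.frames.duration_s) > 1e-9:
            raise ValueError(
                "EMG and frame durations differ: "
                f"{self.emg.duration_s} s vs {self.frames.duration_s} s"
            )


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window configuration shared by both modalities.

    The default 250 ms window with 200 ms step (a literal 50 ms overlap)
    applied to the middle 3 s yields 14 windows per trial at 2000 Hz and,
    with 5-frame windows stepping by 4 frames, the same 14 at 20 Hz.
    """

    window_ms: float = 250.0
    step_ms: float = 200.0
    analysis_span_s: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.step_ms <= self.window_ms:
            raise ValueError("require 0 < step_ms <= window_ms")
        if self.analysis_span_s <= 0:
            raise ValueError("analysis span must be positive")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def step_samples(self, rate: float) -> int:
        return int(round(self.step_ms * rate / 1000.0))


@dataclass
class FeatureMatrix:
    """Windowed feature vectors with aligned labels and provenance.

    Rows are windows; `labels` carries the pattern per row, `subjects` and
    `trials` identify where each window came from (needed for grouped folds
    and per-subject evaluation).
    """

    X: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    trials: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        self.trials = np.asarray(self.trials)
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.subjects) == len(self.trials) == n):
            raise ValueError("rows, labels, subjects, trials must have equal length")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("column names must match feature dimension")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains NaN")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.columns.index(c) for c in names]
        return FeatureMatrix(
            X=self.X[:, idx],
            labels=self.labels,
            subjects=self.subjects,
            trials=self.trials,
            columns=tuple(names),
        )

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask],
            labels=self.labels[mask],
            subjects=self.subjects[mask],
            trials=self.trials[mask],
            columns=self.columns,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.columns))
        df.insert(0, "trial", self.trials)
        df.insert(0, "subject", self.subjects)
        df.insert(0, "label", self.labels)
        return df

    @staticmethod
    def vstack(parts: Iterable["FeatureMatrix"]) -> "FeatureMatrix":
        parts = list(parts)
        if not parts:
            raise ValueError("cannot stack zero feature matrices")
        cols = parts[0].columns
        if any(p.columns != cols for p in parts):
            raise ValueError("column mismatch in vstack")
        return FeatureMatrix(
            X=np.vstack([p.X for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            trials=np.concatenate([p.trials for p in parts]),
            columns=cols,
        )
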