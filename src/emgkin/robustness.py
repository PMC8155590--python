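"""Robustness protocols: EMG noise injection and channel-subset ablation.

Two parameter sweeps over the fusion pipeline:

* Noise sweep — zero-mean Gaussian noise of standard deviation sigma is
  added to the *raw* EMG (before filtering); classifiers are trained on
  clean folds and tested on contaminated held-out folds (by default), for
  sigma in {1e-5, 2e-5, 1e-4}, the magnitudes that matter for raw EMG of
  order 1e-5.  Kinematic features are untouched by construction.

* Channel ablation — every nonempty subset of the 4 EMG channels (15 in
  all: 4 singles, 6 pairs, 4 triples, 1 full set) is evaluated for the EMG
  classifier and both fusion modes (kinematics always complete), emulating
  electrode failure.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data import EMGRecording, FeatureMatrix, WindowingConfig
from .emg import emg_column_names, extract_emg_features
from .fusion import (
    DEFAULT_RIDGE,
    _subject_seed,
    cohort_feature_matrices,
    cross_validate,
)

DEFAULT_NOISE_SIGMAS: tuple[float, ...] = (1e-5, 2e-5, 1e-4)
NOISE_MODES: tuple[str, ...] = ("emg", "feature_fusion", "decision_fusion")


def add_gaussian_noise(rec: EMGRecording, sigma: float, seed: int = 0) -> EMGRecording:
    """Add i.i.d. zero-mean Gaussian noise of sd ``sigma`` to raw EMG samples.

    ``sigma = 0`` returns a bit-identical copy.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return rec.with_samples(rec.samples.copy())
    rng = np.random.default_rng(seed)
    return rec.with_samples(rec.samples + rng.normal(0.0, sigma, rec.samples.shape))


def enumerate_channel_subsets(n_channels: int) -> list[tuple[int, ...]]:
    """All nonempty channel subsets (0-based), ordered by size then lexically."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    out: list[tuple[int, ...]] = []
    for size in range(1, n_channels + 1):
        out.extend(combinations(range(n_channels), size))
    return out


def subset_name(subset: Sequence[int]) -> str:
    """Concatenated-digit subset name (C1, C14, C124, ...), 1-based."""
    return "C" + "".join(str(c + 1) for c in sorted(subset))


@dataclass(frozen=True)
class NoiseSweepSpec:
    sigmas: tuple[float, ...] = DEFAULT_NOISE_SIGMAS
    modes: tuple[str, ...] = NOISE_MODES
    apply_to: str = "test_only"      # or "train_and_test"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigmas):
            raise ValueError("sigmas must be nonnegative")
        if self.apply_to not in ("test_only", "train_and_test"):
            raise ValueError(f"unknown apply_to: {self.apply_to!r}")


@dataclass(frozen=True)
class AblationSpec:
    channel_subsets: tuple[tuple[int, ...], ...] = tuple(enumerate_channel_subsets(4))
    modes: tuple[str, ...] = NOISE_MODES
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.channel_subsets)) != len(self.channel_subsets):
            raise ValueError("channel subsets must be unique")
        if any(len(s) == 0 for s in self.channel_subsets):
            raise ValueError("channel subsets must be nonempty")


def _noisy_emg_features(
    cohort,
    sigma: float,
    cfg: WindowingConfig,
    seed: int,
    sigma_index: int,
) -> FeatureMatrix:
    parts = []
    for t_idx, t in enumerate(cohort.trials):
        noise_seed = int(np.random.SeedSequence(
            [seed, sigma_index, t_idx]).generate_state(1)[0]) & 0x7FFFFFFF
        noisy = add_gaussian_noise(t.emg, sigma, noise_seed)
        parts.append(extract_emg_features(
            noisy, cfg, label=t.label, subject=t.subject_id, trial=t.trial_id,
        ))
    return FeatureMatrix.vstack(parts)


def noise_sweep(
    cohort,
    spec: NoiseSweepSpec = NoiseSweepSpec(),
    cfg: WindowingConfig = WindowingConfig(),
    k: int = 10,
    ridge: float = DEFAULT_RIDGE,
    weights: tuple[float, float] = (0.5, 0.5),
) -> pd.DataFrame:
    """Noise-injection sweep; one row per (sigma, mode, subject).

    Training folds always see clean features under the default
    ``test_only`` protocol; held-out folds see features re-extracted from
    the contaminated raw EMG.  Fold assignments are identical across sigmas,
    so the sigma = 0 row reproduces the clean cross-validation exactly.
    """
    clean_emg, kin_fm = cohort_feature_matrices(cohort, cfg)
    groups = {p.subject_id: p.group for p in cohort.profiles}
    subject_ids = list(dict.fromkeys(clean_emg.subjects.tolist()))
    rows = []
    for s_idx, sigma in enumerate(spec.sigmas):
        if sigma == 0:
            noisy_emg = clean_emg
        else:
            noisy_emg = _noisy_emg_features(cohort, sigma, cfg, spec.seed, s_idx)
        for i, sid in enumerate(subject_ids):
            mask = clean_emg.subjects == sid
            e_clean = clean_emg.subset_rows(mask)
            e_noisy = noisy_emg.subset_rows(mask)
            kn = kin_fm.subset_rows(mask)
            fold_seed = _subject_seed(spec.seed, i)
            for mode in spec.modes:
                if spec.apply_to == "train_and_test":
                    res = cross_validate(e_noisy, kn, mode=mode, k=k,
                                         seed=fold_seed, ridge=ridge,
                                         weights=weights)
                else:
                    res = cross_validate(e_clean, kn, mode=mode, k=k,
                                         seed=fold_seed, ridge=ridge,
                                         weights=weights, test_emg_X=e_noisy)
                rows.append({
                    "sigma": sigma,
                    "mode": mode,
                    "subject": sid,
                    "group": groups[sid],
                    "mean_accuracy": res.mean_accuracy,
                })
    return pd.DataFrame(rows)


def noise_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pivot a noise sweep into the (noise level) x (group, mode) layout."""
    return (
        sweep.groupby(["sigma", "group", "mode"])["mean_accuracy"]
        .mean()
        .unstack(["group", "mode"])
        .sort_index()
    )


def ablation_sweep(
    cohort,
    spec: AblationSpec = AblationSpec(),
    cfg: WindowingConfig = WindowingConfig(),
    k: int = 10,
    ridge: float = DEFAULT_RIDGE,
    weights: tuple[float, float] = (0.5, 0.5),
    include_kin_baseline: bool = True,
) -> pd.DataFrame:
    """Channel-combination ablation; one row per (subset, mode, subject).

    EMG features are extracted once with all channels and subset by column;
    fusion modes always use the complete kinematic features.  The
    kinematics-only baseline is included as subset "kin_only".
    """
    emg_fm, kin_fm = cohort_feature_matrices(cohort, cfg)
    groups = {p.subject_id: p.group for p in cohort.profiles}
    subject_ids = list(dict.fromkeys(emg_fm.subjects.tolist()))
    rows = []
    per_subject = {}
    for i, sid in enumerate(subject_ids):
        mask = emg_fm.subjects == sid
        per_subject[sid] = (
            emg_fm.subset_rows(mask),
            kin_fm.subset_rows(mask),
            _subject_seed(spec.seed, i),
        )
    if include_kin_baseline:
        for sid in subject_ids:
            e, kn, fold_seed = per_subject[sid]
            res = cross_validate(None, kn, mode="kin", k=k, seed=fold_seed,
                                 ridge=ridge, weights=weights)
            rows.append({
                "subset": "kin_only", "size": 0, "mode": "kin",
                "subject": sid, "group": groups[sid],
                "mean_accuracy": res.mean_accuracy,
            })
    for subset in spec.channel_subsets:
        cols = emg_column_names(sorted(subset))
        for sid in subject_ids:
            e, kn, fold_seed = per_subject[sid]
            e_sub = e.select_columns(cols)
            for mode in spec.modes:
                res = cross_validate(e_sub, kn, mode=mode, k=k,
                                     seed=fold_seed, ridge=ridge,
                                     weights=weights)
                rows.append({
                    "subset": subset_name(subset), "size": len(subset),
                    "mode": mode, "subject": sid, "group": groups[sid],
                    "mean_accuracy": res.mean_accuracy,
                })
    return pd.DataFrame(rows)


def ablation_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pivot an ablation sweep into the subset x (group, mode) layout."""
    return (
        sweep.groupby(["size", "subset", "group", "mode"])["mean_accuracy"]
        .mean()
        .unstack(["group", "mode"])
        .sort_index()
    )
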