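"""Trial-bundle readers/writers and the reproducible full-pipeline runner.

On-disk layout (plain delimited text + JSON, diffable):

    <trial_dir>/manifest.json   label, subject, group, rep, rates
    <trial_dir>/emg.csv         '#'-prefixed metadata lines, then
                                time_s, ch1..ch4
    <trial_dir>/frames.csv      metadata lines, then time_s,
                                palm_{x,y,z}, <finger><point>_{x,y,z}

``run_full_pipeline`` ties simulate -> extract -> evaluate -> robustness
into one deterministic run: every output embeds the configuration hash and
all randomness flows from the single root seed via named substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .data import FINGERS, MUSCLES, PATTERNS, EMGRecording, HandFrameSequence, Trial
from .fusion import MODES, evaluate_cohort
from .robustness import (
    AblationSpec,
    NoiseSweepSpec,
    ablation_sweep,
    ablation_table,
    noise_sweep,
    noise_table,
)
from .simulate import Cohort, default_profiles, simulate_cohort


class TrialFormatError(ValueError):
    """A trial bundle file violates the expected schema."""


def _frame_columns() -> list[str]:
    cols = ["time_s", "palm_x", "palm_y", "palm_z"]
    for finger in FINGERS:
        n_pts = 4 if finger == "thumb" else 5
        for j in range(n_pts):
            cols.extend(f"{finger}{j}_{ax}" for ax in ("x", "y", "z"))
    return cols


def write_trial_bundle(path: str | Path, trial: Trial) -> Path:
    """Write one trial as emg.csv + frames.csv + manifest.json under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg = trial.emg
    t = np.arange(emg.n_samples) / emg.fs
    with open(path / "emg.csv", "w") as fh:
        fh.write(f"# fs_hz: {emg.fs}\n")
        fh.write("# muscles: " + " | ".join(emg.channel_names) + "\n")
        header = "time_s," + ",".join(
            f"ch{i + 1}" for i in range(emg.n_channels))
        np.savetxt(fh, np.column_stack([t, emg.samples.T]), delimiter=",",
                   header=header, comments="", fmt="%.17g")
    frames = trial.frames
    blocks = [frames.times[:, None], frames.palm]
    for finger in FINGERS:
        blocks.append(frames.fingers[finger].reshape(len(frames), -1))
    with open(path / "frames.csv", "w") as fh:
        fh.write(f"# fps: {frames.fps}\n")
        np.savetxt(fh, np.hstack(blocks), delimiter=",",
                   header=",".join(_frame_columns()), comments="", fmt="%.17g")
    manifest = {
        "label": trial.label,
        "subject": trial.subject_id,
        "group": trial.group,
        "rep": trial.rep,
        "trial_id": trial.trial_id,
        "fs_hz": emg.fs,
        "fps": frames.fps,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                   sort_keys=True))
    return path


def _read_metadata_lines(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
    return meta


def _read_numeric_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        # +2 for the header line and 1-based counting (metadata lines not counted)
        raise TrialFormatError(
            f"{path.name}: non-numeric value {df.iloc[r, c]!r} in column "
            f"{df.columns[c]!r}, data row {r + 1}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise TrialFormatError(
            f"{path.name}: missing value in column {df.columns[c]!r}, "
            f"data row {r + 1}"
        )
    return numeric


def load_trial_bundle(path: str | Path) -> Trial:
    """Load and validate a trial bundle written by :func:`write_trial_bundle`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    label = manifest.get("label")
    if label not in PATTERNS:
        raise TrialFormatError(
            f"manifest.json: label {label!r} is not one of the 8 patterns"
        )
    emg_meta = _read_metadata_lines(path / "emg.csv")
    emg_df = _read_numeric_table(path / "emg.csv")
    fs = float(emg_meta.get("fs_hz", manifest.get("fs_hz", 0)))
    ch_cols = [c for c in emg_df.columns if c.startswith("ch")]
    muscles = tuple(m.strip() for m in emg_meta.get(
        "muscles", " | ".join(MUSCLES)).split("|"))
    emg = EMGRecording(samples=emg_df[ch_cols].to_numpy().T, fs=fs,
                       channel_names=muscles)
    frame_meta = _read_metadata_lines(path / "frames.csv")
    fdf = _read_numeric_table(path / "frames.csv")
    expected = _frame_columns()
    if list(fdf.columns) != expected:
        raise TrialFormatError(
            f"frames.csv: unexpected columns; first mismatch at "
            f"{next(i for i, (a, b) in enumerate(zip(fdf.columns, expected)) if a != b) if len(fdf.columns) == len(expected) else 'length'}"
        )
    fps = float(frame_meta.get("fps", manifest.get("fps", 0)))
    n = len(fdf)
    fingers = {}
    for finger in FINGERS:
        n_pts = 4 if finger == "thumb" else 5
        cols = [f"{finger}{j}_{ax}" for j in range(n_pts)
                for ax in ("x", "y", "z")]
        fingers[finger] = fdf[cols].to_numpy().reshape(n, n_pts, 3)
    frames = HandFrameSequence(
        times=fdf["time_s"].to_numpy(),
        palm=fdf[["palm_x", "palm_y", "palm_z"]].to_numpy(),
        fingers=fingers,
        fps=fps,
    )
    return Trial(
        label=label,
        emg=emg,
        frames=frames,
        subject_id=manifest.get("subject", ""),
        group=manifest.get("group", ""),
        rep=int(manifest.get("rep", 0)),
        trial_id=manifest.get("trial_id", ""),
    )


def write_cohort(path: str | Path, cohort: Cohort) -> Path:
    """Write every trial bundle plus a cohort-level manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for i, trial in enumerate(cohort.trials):
        tdir = path / f"trial_{i:04d}"
        write_trial_bundle(tdir, trial)
        index.append({
            "dir": tdir.name, "label": trial.label,
            "subject": trial.subject_id, "group": trial.group,
            "rep": trial.rep,
        })
    (path / "cohort.json").write_text(json.dumps(index, indent=2))
    return path


@dataclass(frozen=True)
class RunConfig:
    """Everything a full reproducible run depends on."""

    n_normal: int = 10
    n_stroke: int = 5
    reps_normal: int = 10
    reps_stroke: int = 5
    seed: int = 0
    window_ms: float = 250.0
    step_ms: float = 200.0
    analysis_span_s: float = 3.0
    zc_threshold: float = 0.0
    ssc_threshold: float = 0.0
    folds: int = 10
    ridge: float = 1e-6
    fusion_weights: tuple[float, float] = (0.5, 0.5)
    modes: tuple[str, ...] = MODES
    noise_sigmas: tuple[float, ...] = (1e-5, 2e-5, 1e-4)
    run_noise: bool = True
    run_ablation: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fusion_weights"] = list(self.fusion_weights)
        d["modes"] = list(self.modes)
        d["noise_sigmas"] = list(self.noise_sigmas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("fusion_weights", "modes", "noise_sigmas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def windowing(self):
        from .data import WindowingConfig
        return WindowingConfig(self.window_ms, self.step_ms,
                               self.analysis_span_s)


def demo_config() -> RunConfig:
    """A small configuration that exercises every stage quickly."""
    return RunConfig(n_normal=2, n_stroke=1, reps_normal=3, reps_stroke=3)


def _write_csv(path: Path, df: pd.DataFrame, config_hash: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=index)


def build_cohort(config: RunConfig) -> Cohort:
    profiles = default_profiles(config.n_normal, config.n_stroke, config.seed)
    profiles = [
        replace(p, n_reps=(config.reps_normal if p.group == "normal"
                           else config.reps_stroke))
        for p in profiles
    ]
    return simulate_cohort(profiles)


def run_full_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate, extract, evaluate and sweep; write all result tables.

    Deterministic given the config; every file carries the config hash.
    Returns a dict with the in-memory results.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    cfg = config.windowing()
    stage = "simulate"
    try:
        cohort = build_cohort(config)
        stage = "evaluate"
        results, summary = evaluate_cohort(
            cohort, modes=config.modes, cfg=cfg, k=config.folds,
            seed=config.seed, ridge=config.ridge,
            weights=config.fusion_weights,
        )
        _write_csv(out / "cohort_summary.csv", summary, chash)
        cv_json = {
            sid: {
                mode: {
                    "fold_accuracies": res.fold_accuracies.tolist(),
                    "mean_accuracy": res.mean_accuracy,
                    "confusion": res.confusion.tolist(),
                    "classes": list(res.classes),
                }
                for mode, res in by_mode.items()
            }
            for sid, by_mode in results.items()
        }
        (out / "cv_results.json").write_text(json.dumps(
            {"config_hash": chash, "results": cv_json}, indent=2,
            sort_keys=True))
        noise_df = None
        if config.run_noise:
            stage = "noise_sweep"
            nspec = NoiseSweepSpec(sigmas=tuple(config.noise_sigmas),
                                   seed=config.seed)
            noise_df = noise_sweep(cohort, nspec, cfg, k=config.folds,
                                   ridge=config.ridge,
                                   weights=config.fusion_weights)
            _write_csv(out / "noise_sweep.csv", noise_df, chash)
            _write_csv(out / "noise_table.csv", noise_table(noise_df), chash,
                       index=True)
        abl_df = None
        if config.run_ablation:
            stage = "ablation_sweep"
            aspec = AblationSpec(seed=config.seed)
            abl_df = ablation_sweep(cohort, aspec, cfg, k=config.folds,
                                    ridge=config.ridge,
                                    weights=config.fusion_weights)
            _write_csv(out / "ablation_sweep.csv", abl_df, chash)
            _write_csv(out / "ablation_table.csv", ablation_table(abl_df),
                       chash, index=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    import numpy as _np
    import scipy as _sp

    fs = 2000.0
    windows_per_trial = (
        int(round(cfg.analysis_span_s * fs)) - cfg.window_samples(fs)
    ) // cfg.step_samples(fs) + 1
    provenance = {
        "config": config.to_dict(),
        "config_hash": chash,
        "row_counts": {
            "trials": len(cohort.trials),
            "windows_per_trial": windows_per_trial,
            "summary_rows": int(len(summary)),
        },
        "versions": {"numpy": _np.__version__, "scipy": _sp.__version__},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return {
        "cohort": cohort, "results": results, "summary": summary,
        "noise": noise_df, "ablation": abl_df,
    }
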