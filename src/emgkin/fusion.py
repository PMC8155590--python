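"""LDA classification with feature-level and decision-level fusion.

Four classifier modes are evaluated by stratified k-fold cross-validation
within each subject:

* ``emg``            — LDA on the windowed time-domain EMG features;
* ``kin``            — LDA on the 19-dim kinematic features;
* ``feature_fusion`` — LDA on the column-wise concatenation of both;
* ``decision_fusion``— one LDA per modality, class posteriors superimposed
  (weighted sum, default equal weights) before the argmax.

The discriminant is the Gaussian equal-covariance (pooled) model: class
means are sample means, the shared covariance is the within-class scatter
divided by (n - K) plus a trace-scaled ridge, priors are class frequencies.
Features are z-scored with training-set statistics by default so the ridge
is scale-free across the mixed-unit fused feature space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .data import FeatureMatrix, WindowingConfig
from .emg import extract_emg_features
from .kinematics import extract_kin_features

MODES: tuple[str, ...] = ("emg", "kin", "feature_fusion", "decision_fusion")

DEFAULT_RIDGE = 1e-6


@dataclass(frozen=True)
class LDAModel:
    """Fitted Gaussian equal-covariance discriminant."""

    classes: tuple[str, ...]
    class_means: np.ndarray        # (K, d), on the transformed scale
    pooled_covariance: np.ndarray  # (d, d), symmetric positive definite
    priors: np.ndarray             # (K,), sums to 1
    shift: np.ndarray              # (d,) standardization offset
    scale: np.ndarray              # (d,) standardization divisor

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.shift) / self.scale


def _as_xy(X, labels=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, FeatureMatrix):
        return X.X, X.labels
    if labels is None:
        raise ValueError("labels required when X is a plain array")
    return np.asarray(X, dtype=float), np.asarray(labels)


def fit_lda(
    X,
    labels=None,
    ridge: float = DEFAULT_RIDGE,
    standardize: bool = True,
) -> LDAModel:
    """Fit the pooled-covariance discriminant.

    ``ridge`` scales ``trace(S)/d * I`` added to the pooled covariance S
    (scale-free on standardized features).  Requires >= 2 classes with >= 2
    rows each; with ``ridge=0`` a singular pooled covariance raises
    ``numpy.linalg.LinAlgError``.
    """
    Xa, y = _as_xy(X, labels)
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.shape[0] < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows")
    n, d = Xa.shape
    if standardize:
        shift = Xa.mean(axis=0)
        scale = Xa.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
    else:
        shift = np.zeros(d)
        scale = np.ones(d)
    Z = (Xa - shift) / scale
    k = classes.shape[0]
    means = np.stack([Z[y_idx == j].mean(axis=0) for j in range(k)])
    scatter = np.zeros((d, d))
    for j in range(k):
        c = Z[y_idx == j] - means[j]
        scatter += c.T @ c
    cov = scatter / (n - k)
    if ridge > 0:
        cov = cov + (ridge * np.trace(cov) / d) * np.eye(d)
    # fail loudly on degeneracy rather than producing garbage posteriors
    try:
        linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"pooled covariance is singular (ridge={ridge}); "
            "increase the ridge regularizer"
        ) from exc
    return LDAModel(
        classes=tuple(str(c) for c in classes),
        class_means=means,
        pooled_covariance=cov,
        priors=counts / n,
        shift=shift,
        scale=scale,
    )


def predict_proba(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Class posteriors, rows summing to 1; argmax equals the discriminant argmax."""
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[None, :]
    if Xa.shape[1] != model.n_features:
        raise ValueError(
            f"dimension mismatch: model expects {model.n_features} features, "
            f"got {Xa.shape[1]}"
        )
    Z = model.transform(Xa)
    cho = linalg.cho_factor(model.pooled_covariance)
    scores = np.empty((Z.shape[0], len(model.classes)))
    for j in range(len(model.classes)):
        diff = Z - model.class_means[j]
        maha = np.sum(diff * linalg.cho_solve(cho, diff.T).T, axis=1)
        scores[:, j] = -0.5 * maha + np.log(model.priors[j])
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)
    return p


def predict(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels; ties broken by the lowest class index."""
    p = predict_proba(model, X)
    return np.asarray(model.classes)[np.argmax(p, axis=1)]


def feature_fusion(emg_X: FeatureMatrix, kin_X: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of row-aligned EMG and kinematic features."""
    if emg_X.n_rows != kin_X.n_rows:
        raise ValueError(
            f"row mismatch: {emg_X.n_rows} EMG vs {kin_X.n_rows} kinematic rows"
        )
    if not np.array_equal(emg_X.labels, kin_X.labels):
        raise ValueError("label mismatch between modalities")
    if not np.array_equal(emg_X.trials, kin_X.trials):
        raise ValueError("trial mismatch between modalities")
    return FeatureMatrix(
        X=np.hstack([emg_X.X, kin_X.X]),
        labels=emg_X.labels,
        subjects=emg_X.subjects,
        trials=emg_X.trials,
        columns=emg_X.columns + kin_X.columns,
    )


def decision_fuse(
    p_emg: np.ndarray,
    p_kin: np.ndarray,
    weights: tuple[float, float] = (0.5, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Superimpose two posterior vectors (or row-stacks of them).

    Returns ``(fused_scores, predicted_index)``; prediction is the argmax
    with ties broken toward the lowest class index.
    """
    a = np.atleast_2d(np.asarray(p_emg, dtype=float))
    b = np.atleast_2d(np.asarray(p_kin, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"posterior shape mismatch: {a.shape} vs {b.shape}")
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or (w1 == 0 and w2 == 0):
        raise ValueError("weights must be nonnegative and not both zero")
    fused = w1 * a + w2 * b
    pred = np.argmax(fused, axis=1)
    if np.asarray(p_emg).ndim == 1:
        return fused[0], pred[0]
    return fused, pred


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one subject and one classifier mode."""

    mode: str
    fold_accuracies: np.ndarray
    confusion: np.ndarray
    classes: tuple[str, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _check_alignment(emg_X: FeatureMatrix | None, kin_X: FeatureMatrix | None):
    mats = [m for m in (emg_X, kin_X) if m is not None]
    if not mats:
        raise ValueError("at least one feature matrix is required")
    ref = mats[0]
    for m in mats[1:]:
        if m.n_rows != ref.n_rows or not np.array_equal(m.labels, ref.labels):
            raise ValueError("feature matrices are not row-aligned")
    return ref


def cross_validate(
    emg_X: FeatureMatrix | None = None,
    kin_X: FeatureMatrix | None = None,
    mode: str = "feature_fusion",
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    weights: tuple[float, float] = (0.5, 0.5),
    test_emg_X: FeatureMatrix | None = None,
    test_kin_X: FeatureMatrix | None = None,
    group_by_trial: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one classifier mode.

    Folds are stratified by pattern at the window level (seeded shuffle);
    ``group_by_trial=True`` keeps all windows of a repetition on the same
    side of every split.  ``test_emg_X``/``test_kin_X``, when given, must be
    row-aligned perturbed copies used in place of the clean features for the
    held-out fold only (train-clean / test-perturbed protocols).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "emg" and emg_X is None:
        raise ValueError("mode 'emg' requires emg_X")
    if mode == "kin" and kin_X is None:
        raise ValueError("mode 'kin' requires kin_X")
    if mode in ("feature_fusion", "decision_fusion") and (emg_X is None or kin_X is None):
        raise ValueError(f"mode {mode!r} requires both feature matrices")
    if k < 2:
        raise ValueError("k must be >= 2")
    ref = _check_alignment(emg_X, kin_X)
    for t in (test_emg_X, test_kin_X):
        if t is not None:
            _check_alignment(ref, t)
    labels = ref.labels
    classes, y_idx = np.unique(labels, return_inverse=True)
    if np.bincount(y_idx).min() < k:
        raise ValueError(f"every class needs at least k={k} rows")

    if group_by_trial:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(labels)), y_idx, groups=ref.trials)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(labels)), y_idx)

    te_emg = test_emg_X if test_emg_X is not None else emg_X
    te_kin = test_kin_X if test_kin_X is not None else kin_X

    n_cls = len(classes)
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    fold_acc: list[float] = []
    for train_idx, test_idx in splits:
        y_test = y_idx[test_idx]
        if mode == "emg":
            model = fit_lda(emg_X.X[train_idx], labels[train_idx], ridge)
            p = predict_proba(model, te_emg.X[test_idx])
            pred = np.argmax(p, axis=1)
        elif mode == "kin":
            model = fit_lda(kin_X.X[train_idx], labels[train_idx], ridge)
            p = predict_proba(model, te_kin.X[test_idx])
            pred = np.argmax(p, axis=1)
        elif mode == "feature_fusion":
            Xtr = np.hstack([emg_X.X[train_idx], kin_X.X[train_idx]])
            Xte = np.hstack([te_emg.X[test_idx], te_kin.X[test_idx]])
            model = fit_lda(Xtr, labels[train_idx], ridge)
            p = predict_proba(model, Xte)
            pred = np.argmax(p, axis=1)
        else:  # decision_fusion
            m_emg = fit_lda(emg_X.X[train_idx], labels[train_idx], ridge)
            m_kin = fit_lda(kin_X.X[train_idx], labels[train_idx], ridge)
            p_e = predict_proba(m_emg, te_emg.X[test_idx])
            p_k = predict_proba(m_kin, te_kin.X[test_idx])
            _, pred = decision_fuse(p_e, p_k, weights)
        fold_acc.append(float(np.mean(pred == y_test)))
        np.add.at(confusion, (y_test, pred), 1)
    return CVResult(
        mode=mode,
        fold_accuracies=np.asarray(fold_acc),
        confusion=confusion,
        classes=tuple(str(c) for c in classes),
    )


def cohort_feature_matrices(
    cohort,
    cfg: WindowingConfig = WindowingConfig(),
    channels: Sequence[int] | None = None,
    zc_threshold: float = 0.0,
    ssc_threshold: float = 0.0,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Row-aligned (EMG, kinematic) feature matrices for a whole cohort."""
    emg_parts = []
    kin_parts = []
    for t in cohort.trials:
        emg_parts.append(extract_emg_features(
            t.emg, cfg, channels, zc_threshold, ssc_threshold,
            label=t.label, subject=t.subject_id, trial=t.trial_id,
        ))
        kin_parts.append(extract_kin_features(
            t.frames, cfg, label=t.label, subject=t.subject_id,
            trial=t.trial_id,
        ))
    emg_fm = FeatureMatrix.vstack(emg_parts)
    kin_fm = FeatureMatrix.vstack(kin_parts)
    assert emg_fm.n_rows == kin_fm.n_rows, "modalities lost row alignment"
    return emg_fm, kin_fm


def _subject_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0]) & 0x7FFFFFFF


def evaluate_subjects(
    emg_fm: FeatureMatrix,
    kin_fm: FeatureMatrix,
    modes: Sequence[str] = MODES,
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    weights: tuple[float, float] = (0.5, 0.5),
    group_by_trial: bool = False,
) -> dict[str, dict[str, CVResult]]:
    """Per-subject cross-validation of each requested mode.

    One classifier per subject: rows are partitioned by subject id and each
    subject gets an independently seeded fold assignment.
    """
    results: dict[str, dict[str, CVResult]] = {}
    subject_ids = list(dict.fromkeys(emg_fm.subjects.tolist()))
    for i, sid in enumerate(subject_ids):
        mask = emg_fm.subjects == sid
        e = emg_fm.subset_rows(mask)
        kn = kin_fm.subset_rows(mask)
        s_seed = _subject_seed(seed, i)
        results[sid] = {
            mode: cross_validate(e, kn, mode=mode, k=k, seed=s_seed,
                                 ridge=ridge, weights=weights,
                                 group_by_trial=group_by_trial)
            for mode in modes
        }
    return results


def aggregate_cohort(
    results: Mapping[str, Mapping[str, CVResult]],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Cohort summary: per (group, mode) mean and sd of per-subject accuracies."""
    if not results:
        raise ValueError("need at least one subject")
    rows = []
    modes = list(next(iter(results.values())).keys())
    group_names = list(dict.fromkeys(groups[s] for s in results))
    for grp in group_names:
        sids = [s for s in results if groups[s] == grp]
        for mode in modes:
            vals = np.array([results[s][mode].mean_accuracy for s in sids])
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append({
                "group": grp,
                "mode": mode,
                "mean_accuracy": float(vals.mean()),
                "sd_accuracy": sd,
                "n_subjects": len(vals),
            })
    return pd.DataFrame(rows)


def evaluate_cohort(
    cohort,
    modes: Sequence[str] = MODES,
    cfg: WindowingConfig = WindowingConfig(),
    k: int = 10,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    weights: tuple[float, float] = (0.5, 0.5),
    channels: Sequence[int] | None = None,
    group_by_trial: bool = False,
) -> tuple[dict[str, dict[str, CVResult]], pd.DataFrame]:
    """Feature extraction + per-subject CV + cohort aggregation in one call."""
    emg_fm, kin_fm = cohort_feature_matrices(cohort, cfg, channels)
    results = evaluate_subjects(emg_fm, kin_fm, modes, k, seed, ridge,
                                weights, group_by_trial)
    groups = {p.subject_id: p.group for p in cohort.profiles}
    return results, aggregate_cohort(results, groups)
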