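"""LDA fitting, posterior computation, fusion modes, and cross-validation."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from emgkin import (
    MODES,
    FeatureMatrix,
    aggregate_cohort,
    cross_validate,
    decision_fuse,
    feature_fusion,
    fit_lda,
    predict,
    predict_proba,
)


def _blobs(rng, means, n_per=60, sd=0.3):
    X = np.vstack([m + sd * rng.normal(size=(n_per, len(m))) for m in means])
    y = np.concatenate([[f"c{i}"] * n_per for i in range(len(means))])
    return X, y


class TestFitLDA:
    def test_separated_classes_train_perfectly(self, rng):
        X, y = _blobs(rng, [(0.0, 0.0), (3.0, 3.0)], n_per=200, sd=0.1)
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        assert np.mean(predict(model, X) == y) == 1.0

    def test_identical_classes_give_prior_posteriors(self, rng):
        Xc = rng.normal(size=(50, 3))
        X = np.vstack([Xc, Xc])
        y = np.array(["a"] * 50 + ["b"] * 50)
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        p = predict_proba(model, Xc)
        np.testing.assert_allclose(p, 0.5, atol=1e-9)

    def test_posteriors_sum_to_one(self, rng):
        X, y = _blobs(rng, [(0, 0, 0), (1, 1, 0), (0, 2, 1)])
        model = fit_lda(X, y)
        p = predict_proba(model, rng.normal(size=(40, 3)) * 5)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_small_class_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_lda(X, np.array(["a", "a", "b"]))

    def test_singular_covariance_without_ridge_raises(self):
        X = np.zeros((8, 2))
        X[:, 0] = np.arange(8)  # second feature constant -> singular
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(np.linalg.LinAlgError):
            fit_lda(X, y, ridge=0.0, standardize=False)


class TestPredictProba:
    def test_matches_brute_force_gaussian_discriminant(self, rng):
        """Posteriors equal prior x Gaussian(pooled covariance) likelihood,
        evaluated directly with scipy densities, on 50 random points."""
        X, y = _blobs(rng, [(0, 0, 0), (2, 0, 1), (0, 3, -1)], n_per=20)
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        pts = rng.normal(size=(50, 3)) * 2
        p = predict_proba(model, pts)
        dens = np.stack([
            model.priors[j] * multivariate_normal.pdf(
                pts, mean=model.class_means[j], cov=model.pooled_covariance)
            for j in range(3)
        ], axis=1)
        np.testing.assert_allclose(p, dens / dens.sum(axis=1, keepdims=True),
                                   rtol=1e-8, atol=1e-12)

    def test_point_at_class_mean_wins(self, rng):
        X, y = _blobs(rng, [(0.0, 0.0), (4.0, 0.0)], n_per=30, sd=0.5)
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        p = predict_proba(model, model.class_means[1])
        assert np.argmax(p) == 1

    def test_equidistant_point_ties(self):
        X = np.array([[-1.1, 0.1], [-0.9, -0.1], [1.1, 0.1], [0.9, -0.1]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_lda(X, y, ridge=0.0, standardize=False)
        p = predict_proba(model, np.array([0.0, 0.0]))[0]
        np.testing.assert_allclose(p[0], p[1], atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        X, y = _blobs(rng, [(0, 0), (1, 1)])
        model = fit_lda(X, y)
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((5, 3)))

    def test_predictions_match_sklearn_lda(self, rng):
        """Independent cross-check against scikit-learn's estimator on
        moderately separated blobs."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = _blobs(rng, [(0, 0, 0), (1.5, 0, 1), (0, 2, 0.5)], n_per=80,
                      sd=0.6)
        ours = predict(fit_lda(X, y, ridge=0.0, standardize=False), X)
        ref = LinearDiscriminantAnalysis().fit(X, y).predict(X)
        assert np.mean(ours == ref) > 0.99


def _fm(X, labels, columns=None, trial="t0"):
    n = len(labels)
    return FeatureMatrix(
        X=X, labels=np.asarray(labels),
        subjects=np.array(["s"] * n), trials=np.array([trial] * n),
        columns=tuple(columns or (f"f{i}" for i in range(X.shape[1]))),
    )


class TestFeatureFusion:
    def test_concatenation_dimensions(self, small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        fused = feature_fusion(emg_fm, kin_fm)
        assert fused.X.shape[1] == 20 + 19  # 5 x 4 channels + 19 kinematics
        np.testing.assert_array_equal(fused.labels, emg_fm.labels)

    def test_row_misalignment_rejected(self, rng):
        a = _fm(rng.normal(size=(4, 2)), ["x", "x", "y", "y"])
        b = _fm(rng.normal(size=(3, 2)), ["x", "y", "y"])
        with pytest.raises(ValueError):
            feature_fusion(a, b)
        c = _fm(rng.normal(size=(4, 2)), ["x", "y", "x", "y"])
        with pytest.raises(ValueError):
            feature_fusion(a, c)


class TestDecisionFuse:
    def test_weighted_superposition(self):
        fused, pred = decision_fuse([0.6, 0.4], [0.3, 0.7])
        np.testing.assert_allclose(fused, [0.45, 0.55])
        assert pred == 1

    def test_degenerate_weights_reduce_to_single_modality(self):
        fused, pred = decision_fuse([0.2, 0.8], [0.9, 0.1], weights=(1.0, 0.0))
        assert pred == 1
        np.testing.assert_allclose(fused, [0.2, 0.8])

    def test_tie_breaks_to_lowest_class_index(self):
        _, pred = decision_fuse([0.5, 0.5], [0.5, 0.5])
        assert pred == 0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            decision_fuse([0.5, 0.5], [0.3, 0.3, 0.4])
        with pytest.raises(ValueError):
            decision_fuse([0.5, 0.5], [0.5, 0.5], weights=(0.0, 0.0))


class TestCrossValidate:
    def test_folds_partition_rows_exactly_once(self, rng):
        from sklearn.model_selection import StratifiedKFold

        y = np.repeat(np.arange(4), 30)
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        seen = np.zeros(len(y), dtype=int)
        for _, test_idx in splitter.split(np.zeros(len(y)), y):
            seen[test_idx] += 1
        assert np.all(seen == 1)

    def test_well_separated_subject_above_95_all_modes(self,
                                                       small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        mask = emg_fm.subjects == "N01"
        e, kf = emg_fm.subset_rows(mask), kin_fm.subset_rows(mask)
        for mode in MODES:
            res = cross_validate(e, kf, mode=mode, k=10, seed=0)
            assert res.mean_accuracy >= 0.95, mode

    def test_confusion_rows_sum_to_class_counts(self, small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        mask = emg_fm.subjects == "P01"
        e, kf = emg_fm.subset_rows(mask), kin_fm.subset_rows(mask)
        res = cross_validate(e, kf, mode="feature_fusion", k=10, seed=0)
        counts = {c: int(np.sum(e.labels == c)) for c in res.classes}
        np.testing.assert_array_equal(
            res.confusion.sum(axis=1), [counts[c] for c in res.classes])

    def test_degenerate_decision_fusion_equals_emg_only(self,
                                                        small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        mask = emg_fm.subjects == "N01"
        e, kf = emg_fm.subset_rows(mask), kin_fm.subset_rows(mask)
        a = cross_validate(e, kf, mode="emg", k=10, seed=5)
        b = cross_validate(e, kf, mode="decision_fusion", k=10, seed=5,
                           weights=(1.0, 0.0))
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)

    def test_fold_determinism(self, small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        mask = emg_fm.subjects == "N01"
        e, kf = emg_fm.subset_rows(mask), kin_fm.subset_rows(mask)
        a = cross_validate(e, kf, mode="feature_fusion", k=10, seed=3)
        b = cross_validate(e, kf, mode="feature_fusion", k=10, seed=3)
        np.testing.assert_array_equal(a.fold_accuracies, b.fold_accuracies)
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_class_smaller_than_k_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        fm = _fm(X, y)
        with pytest.raises(ValueError):
            cross_validate(fm, None, mode="emg", k=10)


class TestAggregate:
    def test_single_subject_summary(self, small_cohort_features):
        emg_fm, kin_fm = small_cohort_features
        mask = emg_fm.subjects == "N01"
        res = cross_validate(emg_fm.subset_rows(mask),
                             kin_fm.subset_rows(mask), mode="emg", k=10, seed=0)
        df = aggregate_cohort({"N01": {"emg": res}}, {"N01": "normal"})
        assert df.loc[0, "mean_accuracy"] == pytest.approx(res.mean_accuracy)
        assert df.loc[0, "sd_accuracy"] == 0.0

    def test_two_subject_mean_and_permutation_invariance(self):
        class FakeRes:
            def __init__(self, acc):
                self.mean_accuracy = acc

        r = {"a": {"emg": FakeRes(0.8)}, "b": {"emg": FakeRes(1.0)}}
        g = {"a": "normal", "b": "normal"}
        df1 = aggregate_cohort(r, g)
        assert df1.loc[0, "mean_accuracy"] == pytest.approx(0.9)
        r2 = {"b": r["b"], "a": r["a"]}
        df2 = aggregate_cohort(r2, g)
        assert df2.loc[0, "mean_accuracy"] == pytest.approx(0.9)
        assert df2.loc[0, "sd_accuracy"] == pytest.approx(
            df1.loc[0, "sd_accuracy"])
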