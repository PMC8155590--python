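"""Synthetic-data generator: templates, EMG/kinematics synthesis, cohorts."""

import numpy as np
import pytest

from emgkin import (
    PATTERNS,
    SubjectProfile,
    cohort_feature_matrices,
    cross_validate,
    make_default_templates,
    normal_profile,
    sequence_features,
    simulate_cohort,
    simulate_emg,
    simulate_kinematics,
    template_from_angles,
)


class TestTemplates:
    def test_eight_pairwise_distinct_templates(self, templates):
        assert set(templates) == set(PATTERNS)
        sigs = [templates[p].kinematic_signature for p in PATTERNS]
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.linalg.norm(sigs[i] - sigs[j]) > 0

    def test_hand_open_is_fully_extended_maximum(self, templates):
        open_t = templates["hand_open"]
        assert np.allclose(open_t.target_angles, 180.0)
        fist = templates["fist"]
        assert np.all(fist.target_angles < open_t.target_angles)
        assert np.all(fist.target_distances < open_t.target_distances)
        # full extension maximizes every fingertip-palm distance
        for p in PATTERNS:
            assert np.all(templates[p].target_distances
                          <= open_t.target_distances + 1e-9)

    def test_template_invariant_validation(self):
        with pytest.raises(ValueError):
            template_from_angles("fist", np.full(14, 200.0), np.ones(4))
        with pytest.raises(ValueError):
            template_from_angles("fist", np.full(14, 150.0), -np.ones(4))


class TestSimulateEMG:
    def test_sample_count_and_determinism(self, templates):
        prof = normal_profile("N01", seed=0)
        rec1 = simulate_emg(templates["fist"], prof, duration_s=5.0,
                            fs=2000.0, seed=7)
        rec2 = simulate_emg(templates["fist"], prof, duration_s=5.0,
                            fs=2000.0, seed=7)
        assert rec1.samples.shape == (4, 10000)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        rec3 = simulate_emg(templates["fist"], prof, seed=8)
        assert not np.array_equal(rec1.samples, rec3.samples)

    def test_invalid_arguments(self, templates):
        prof = normal_profile("N01", seed=0)
        with pytest.raises(ValueError):
            simulate_emg(templates["fist"], prof, duration_s=0.0)
        with pytest.raises(ValueError):
            simulate_emg(templates["fist"], prof, fs=-1.0)

    def test_mav_matches_gaussian_absolute_moment(self):
        """Mean window MAV ~ sigma * sqrt(2/pi), the Gaussian E|X| closed form."""
        sigma = 2e-5
        tpl = template_from_angles(
            "fist", np.full(14, 150.0), np.full(4, sigma))
        prof = SubjectProfile("S", emg_noise_floor=0.0, amplitude_jitter=0.0)
        mavs = []
        for seed in range(100):
            rec = simulate_emg(tpl, prof, duration_s=1.0, fs=2000.0, seed=seed)
            win = rec.samples[:, :500]
            mavs.append(np.abs(win).mean())
        expected = sigma * np.sqrt(2.0 / np.pi)
        assert abs(np.mean(mavs) - expected) < 0.2 * expected

    def test_magnitude_scale_is_realistic(self, templates):
        """Default samples have IQR within [1e-6, 1e-4] so the noise protocol
        perturbs at meaningful amplitudes."""
        prof = normal_profile("N01", seed=0)
        recs = [simulate_emg(templates[p], prof, seed=i)
                for i, p in enumerate(PATTERNS)]
        samples = np.concatenate([r.samples.ravel() for r in recs])
        q25, q75 = np.percentile(np.abs(samples), [25, 75])
        assert 1e-6 <= q25 <= q75 <= 1e-4


class TestSimulateKinematics:
    def test_frame_count_and_determinism(self, templates):
        prof = normal_profile("N01", seed=0)
        seq1 = simulate_kinematics(templates["fist"], prof, duration_s=5.0,
                                   fps=20.0, seed=3)
        seq2 = simulate_kinematics(templates["fist"], prof, duration_s=5.0,
                                   fps=20.0, seed=3)
        assert len(seq1) == 100
        np.testing.assert_array_equal(seq1.palm, seq2.palm)
        for f in seq1.fingers:
            np.testing.assert_array_equal(seq1.fingers[f], seq2.fingers[f])

    def test_zero_jitter_recovers_targets_exactly(self, templates):
        prof = SubjectProfile("S", kinematic_jitter_deg=0.0, pose_drift_deg=0.0)
        for pid in ("hand_open", "fist", "lateral_pinch"):
            tpl = templates[pid]
            seq = simulate_kinematics(tpl, prof, seed=0)
            feats = sequence_features(seq)
            np.testing.assert_allclose(
                feats, np.tile(tpl.kinematic_signature, (len(seq), 1)),
                atol=1e-9)

    def test_recovered_angle_spread_matches_jitter(self, templates):
        """Per-angle sd over 1000 frames lies in the chi-distribution CI for
        a true sd of 2 degrees."""
        prof = SubjectProfile("S", kinematic_jitter_deg=2.0, pose_drift_deg=0.0)
        seq = simulate_kinematics(templates["fist"], prof, duration_s=50.0,
                                  fps=20.0, seed=4)
        angles = sequence_features(seq)[:, :14]
        sds = angles.std(axis=0, ddof=1)
        assert np.all(sds > 1.7) and np.all(sds < 2.3)

    def test_invalid_arguments(self, templates):
        prof = normal_profile("N01", seed=0)
        with pytest.raises(ValueError):
            simulate_kinematics(templates["fist"], prof, duration_s=-1.0)
        with pytest.raises(ValueError):
            simulate_kinematics(templates["fist"], prof, fps=0.0)


class TestSimulateCohort:
    def test_trial_counts_and_label_balance(self):
        profiles = [normal_profile(f"N{i:02d}", seed=i) for i in range(10)]
        cohort = simulate_cohort(profiles, duration_s=1.0)
        assert len(cohort.trials) == 800  # 10 subjects x 8 patterns x 10 reps
        for sid in cohort.subject_ids:
            labels = [t.label for t in cohort.trials_of(sid)]
            for p in PATTERNS:
                assert labels.count(p) == 10

    def test_stroke_cohort_counts(self):
        from emgkin import stroke_profile

        profiles = [stroke_profile(f"P{i:02d}", seed=i) for i in range(5)]
        cohort = simulate_cohort(profiles, duration_s=1.0)
        assert len(cohort.trials) == 200  # 5 x 8 x 5

    def test_cohort_determinism(self):
        profiles = [normal_profile("N01", seed=42)]
        c1 = simulate_cohort(profiles, duration_s=1.0)
        c2 = simulate_cohort(profiles, duration_s=1.0)
        for t1, t2 in zip(c1.trials, c2.trials):
            assert t1.label == t2.label
            np.testing.assert_array_equal(t1.emg.samples, t2.emg.samples)
            np.testing.assert_array_equal(t1.frames.palm, t2.frames.palm)

    def test_missing_template_rejected(self, templates):
        incomplete = {k: v for k, v in templates.items() if k != "fist"}
        with pytest.raises(ValueError, match="fist"):
            simulate_cohort([normal_profile("N01", seed=0)], incomplete)

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            simulate_cohort([])


def _blended_templates(alpha: float):
    """Shrink every pose toward the grand-mean pose by 1 - alpha."""
    base = make_default_templates()
    mean = np.mean([t.target_angles for t in base.values()], axis=0)
    return {
        pid: template_from_angles(
            pid, mean + alpha * (t.target_angles - mean), t.muscle_activation)
        for pid, t in base.items()
    }


def test_kinematic_accuracy_monotone_in_template_separation():
    """Pulling the 8 poses apart never hurts kinematics-only accuracy
    (averaged over 10 cohort seeds)."""
    accs = {}
    for alpha in (0.25, 1.0):
        tpls = _blended_templates(alpha)
        vals = []
        for seed in range(10):
            prof = SubjectProfile(f"S{seed}", n_reps=4, seed=seed)
            cohort = simulate_cohort([prof], tpls)
            _, kin_fm = cohort_feature_matrices(cohort)
            res = cross_validate(None, kin_fm, mode="kin", k=10, seed=seed)
            vals.append(res.mean_accuracy)
        accs[alpha] = np.mean(vals)
    assert accs[1.0] >= accs[0.25]
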