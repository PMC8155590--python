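"""Shared fixtures: templates, small cohorts, and the multi-seed study
feature matrices reused by the heavier evaluation tests."""

from __future__ import annotations

import numpy as np
import pytest

from emgkin import (
    cohort_feature_matrices,
    default_profiles,
    make_default_templates,
    normal_profile,
    simulate_cohort,
    stroke_profile,
)

#: Cohort seeds over which the stochastic study properties are averaged.
STUDY_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def templates():
    return make_default_templates()


@pytest.fixture(scope="session")
def small_cohort():
    """One normal + one post-stroke subject, full-length trials."""
    return simulate_cohort(
        [normal_profile("N01", seed=1), stroke_profile("P01", seed=2)]
    )


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return cohort_feature_matrices(small_cohort)


@pytest.fixture(scope="session")
def study_features():
    """Clean feature matrices of the default 10+5 cohort for each study seed.

    Keyed by cohort seed; each entry is (emg_fm, kin_fm, groups).  Raw
    signals are dropped after extraction to keep memory bounded; tests that
    need raw EMG (noise injection) regenerate the cohort from its seed.
    """
    out = {}
    for seed in STUDY_SEEDS:
        cohort = simulate_cohort(default_profiles(seed=seed))
        emg_fm, kin_fm = cohort_feature_matrices(cohort)
        groups = {p.subject_id: p.group for p in cohort.profiles}
        out[seed] = (emg_fm, kin_fm, groups)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
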