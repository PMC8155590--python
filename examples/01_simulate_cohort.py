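"""Simulate a small synchronized EMG + hand-skeleton cohort and inspect it.

Builds one virtual normal subject (10 repetitions of each of the 8 hand
patterns, 5-s holds) and prints the shape and scale of the generated
signals.  Every trial is a pure function of the profile seed.
"""

import numpy as np

import emgkin as ek

cohort = ek.simulate_cohort([ek.normal_profile("N01", seed=1)])
print(f"trials: {len(cohort.trials)}  (8 patterns x 10 reps)")

trial = cohort.trials[0]
print(f"first trial: pattern={trial.label!r}")
print(f"  EMG: {trial.emg.samples.shape} samples at {trial.emg.fs:.0f} Hz "
      f"from {trial.emg.channel_names[0]}, ...")
q25, q75 = np.percentile(np.abs(trial.emg.samples), [25, 75])
print(f"  |EMG| interquartile range: [{q25:.2e}, {q75:.2e}] signal units")
print(f"  frames: {len(trial.frames)} at {trial.frames.fps:.0f} fps")

# The templates behind the cohort: hand_open is fully extended (all 180 deg)
templates = ek.make_default_templates()
open_t = templates["hand_open"]
fist_t = templates["fist"]
print(f"hand_open angles: {open_t.target_angles.min():.0f}-"
      f"{open_t.target_angles.max():.0f} deg, "
      f"fingertip distances {np.round(open_t.target_distances, 1)} mm")
print(f"fist      angles: {fist_t.target_angles.min():.0f}-"
      f"{fist_t.target_angles.max():.0f} deg, "
      f"fingertip distances {np.round(fist_t.target_distances, 1)} mm")
# Expect: EMG magnitudes of order 1e-5 and fist distances far below
# hand_open's -- the amplitude and pose structure the classifier exploits.
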