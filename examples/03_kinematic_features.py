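"""Hand-skeleton kinematic features: 14 joint angles + 5 fingertip distances.

Shows the per-frame 19-vector, the zero-noise round trip (generator pose ->
extractor features), and window averaging aligned with the EMG windows.
"""

import numpy as np

import emgkin as ek

# A fully open hand attains the 180-deg maximum at every joint
open_frame = ek.pose_from_angles(np.full(14, 180.0))
feats = ek.frame_features(open_frame)
print(f"19-dim feature vector: {feats.shape[0]} values "
      f"({ek.KIN_FEATURE_NAMES[:3]} ... {ek.KIN_FEATURE_NAMES[-2:]})")
print("open-hand angles:", np.round(feats[:14], 6))
print("open-hand fingertip-palm distances (mm):", np.round(feats[14:], 1))

# Round trip: a noise-free simulated hold reproduces the template exactly
templates = ek.make_default_templates()
quiet = ek.SubjectProfile("S", kinematic_jitter_deg=0.0, pose_drift_deg=0.0)
seq = ek.simulate_kinematics(templates["lateral_pinch"], quiet, seed=0)
fm = ek.extract_kin_features(seq)
err = np.max(np.abs(fm.X - templates["lateral_pinch"].kinematic_signature))
print(f"zero-jitter round-trip error: {err:.2e} (deg/mm)")

# With realistic jitter the windows scatter around the template pose
noisy = ek.normal_profile("N01", seed=1)
seq = ek.simulate_kinematics(templates["lateral_pinch"], noisy, seed=0)
fm = ek.extract_kin_features(seq)
print(f"windows: {fm.X.shape[0]} (matches the EMG window count), "
      f"per-angle sd across windows ~ "
      f"{fm.X[:, :14].std(axis=0).mean():.2f} deg")
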