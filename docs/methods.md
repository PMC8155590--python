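# Methods

## Problem and pipeline

`emgkin` classifies which of eight static hand patterns of daily living
(finger bend, finger close, finger flexion, hand open, lateral pinch,
fingertip-to-fingertip, fist, cylindrical grip) a subject is holding, from
two synchronized streams: four-channel surface EMG (abductor pollicis
brevis, flexor carpi radialis, extensor digitorum, extensor carpi ulnaris;
2000 Hz) and a markerless hand-skeleton stream (20 fps). The intended
application is intent recognition for hand rehabilitation and assistive
robotics, where EMG alone is often unreliable in post-stroke users.

Per 5-s hold, the middle 3 s are analyzed. Both modalities are segmented
with the same sliding window, 250 ms long stepping by 200 ms (a literal
50 ms overlap), giving 14 aligned windows per trial at the native rates.

**EMG features.** The raw signal is band-pass filtered (2nd-order
Butterworth, 20–500 Hz) and each window of each channel yields five
time-domain features:

- MAV = (1/N) Σ |x_i|
- ZC = #{i : x_i·x_{i+1} < 0 and |x_i − x_{i+1}| > θ_zc}
- SSC = #{i : (x_i − x_{i−1})(x_i − x_{i+1}) > θ_ssc}
- DAMV = (1/N) Σ_{i=1}^{N−1} |x_{i+1} − x_i|
- VAR = (1/(N−1)) Σ x_i²

VAR is deliberately *uncentered* and DAMV divides N−1 terms by N; these are
the definitions this pipeline implements (a conventional centered variance
is available behind `centered_var=True`). The ZC/SSC thresholds default to
0: the synthetic signals carry no DC offset, and a deterministic documented
default beats an unstated one. The filter is applied zero-phase
(forward–backward) by default so no group delay desynchronizes EMG windows
from kinematic windows; this squares the magnitude response, which the
filter tests account for. A causal option exists. When the upper band edge
would reach Nyquist, it is clipped to 0.99·(fs/2) so the design stays valid.

**Kinematic features.** Each frame contributes a 19-vector: 14 interior
joint angles (thumb T1–T2 — the thumb has no metacarpal, hence two joints —
then index/middle/ring/little with three joints each) and 5 fingertip-to-
palm-center Euclidean distances (thumb→little). The joint angle between
bone vectors u (joint → proximal bone end) and v (joint → distal bone end)
is arccos(u·v/|u||v|), oriented so full extension gives the 180° maximum;
it is evaluated as atan2(|u×v|, u·v), which is algebraically identical but
well-conditioned at 0° and 180° (no clamping artifacts, no NaN on
numerically super-parallel vectors). Frames in each window are averaged
(5 frames per window at 20 fps), so kinematic rows align one-to-one with
EMG rows. Window assignment is index-based with the same
floor((T−W)/S)+1 rule as the EMG segmenter — at nominal rates this is
exactly equivalent to matching frame timestamps against EMG window spans
and guarantees row alignment by construction.

**Classifier.** Linear discriminant analysis as the Gaussian
equal-covariance model: per-class sample means, pooled covariance
(within-class scatter / (n−K)) plus a trace-scaled ridge λ·tr(S)/d·I,
priors from class frequencies; posteriors by softmax of the discriminants.
Features are z-scored with training-fold statistics inside `fit_lda` by
default: the fused feature space mixes units (volts ~1e−5 against degrees
~1e2), and without standardization any single ridge either drowns the EMG
block or fails to regularize the kinematic block. λ defaults to 1e−6,
large enough to guarantee a usable Cholesky factor on near-degenerate
synthetic features and ~6 orders below the standardized eigenvalue scale;
with λ=0 a singular covariance raises rather than returning garbage. Ties
in the posterior argmax break toward the lowest class index, everywhere.

**Fusion.** Feature fusion concatenates the 5·(#channels) EMG columns with
the 19 kinematic columns before a single LDA. Decision fusion trains one
LDA per modality and superimposes posteriors as w₁·p_emg + w₂·p_kin
(default ½/½) before the argmax — "superimposed" is read as additive;
product fusion is out of scope.

**Evaluation.** Stratified 10-fold cross-validation *within each subject*
(one classifier per subject; no cross-subject pooling), folds stratified by
pattern at the window level with a seeded shuffle; `group_by_trial=True`
instead keeps all windows of a repetition on one side of each split —
window-level folding is the default. Cohort summaries report mean ± sd of
per-subject mean accuracies, separately for the normal and post-stroke
groups (sd over one subject is reported as 0).

**Robustness protocols.** (1) Noise: i.i.d. zero-mean Gaussian noise of sd
σ ∈ {1e−5, 2e−5, 1e−4} — meaningful perturbations for raw EMG of order
1e−5 — is added to the *raw* EMG before filtering; classifiers are trained
on clean folds and tested on contaminated held-out folds (`test_only`
default, a `train_and_test` option exists). Fold seeds are shared across σ,
so σ=0 reproduces the clean evaluation bit-for-bit. Kinematic results are
invariant to EMG noise by construction. (2) Ablation: all 2⁴−1 = 15
nonempty EMG channel subsets (named C1, C14, C124, … by 1-based channel
digits), evaluated for the EMG-only classifier and both fusion modes, with
kinematics always complete, plus a kinematics-only baseline row.

## Synthetic cohort generator

No public recordings exist for this protocol, so the package ships a
first-class generator whose defaults *are* the study conditions: 10 normal
virtual subjects with 10 repetitions per pattern and 5 post-stroke subjects
with 5 repetitions, 5-s holds, 4-channel EMG at 2000 Hz, 20 fps skeleton
frames.

*EMG* is amplitude-modulated band-limited Gaussian noise: per channel,
white Gaussian noise filtered to 20–450 Hz, normalized to unit sample sd,
scaled by (pattern activation amplitude) × (subject attenuation) × (a
per-trial lognormal effort factor, sd 0.2 for normals), plus a white noise
floor (2e−6 normal, 4e−6 post-stroke). The interference-noise surrogate
makes window statistics analytically checkable: for envelope σ the expected
MAV is σ√(2/π). Default activation amplitudes lie in 0.7–3.5 × 1e−5 and the
default sample-magnitude IQR sits inside [1e−6, 1e−4].

*Kinematics* realizes each pattern's 14 target joint angles with a
planar-chain skeleton: each finger is a 3–4 bone chain with fixed
anthropometric bone lengths (mm), confined to its own plane, curling toward
the palm normal; per-frame angles are target + per-trial drift (sd 2°
normal / 4° post-stroke) + per-frame jitter (sd 3° / 6°). Because the
fingertip–palm distances of a chain are a function of its angles, template
target distances are *measured off the realized zero-noise pose*, which
makes the generator→extractor round-trip exact by construction.

*Post-stroke impairment* is a single attenuation-plus-jitter knob
(activation ×0.6, both kinematic noise terms doubled, effort sd 0.35): the
group is separably harder in both modalities without inventing unreported
pathophysiology.

*Built-in confusions.* Two template pairs are deliberately hard in exactly
one modality: finger_close is kinematically near hand_open (near-straight
fingers) but muscularly distinct, and cylindrical_grip has EMG amplitudes
close to fist but a clearly different pose. Each single modality therefore
has a characteristic error mode and fusion resolves both — the structure
the fusion comparison probes.

*What the generator does not emulate:* motor-unit physiology, powerline or
motion artifacts, electrode shift, inter-muscle crosstalk, tracking
occlusions or dropped frames, and realistic inter-subject anatomical
variation. Passing the suite therefore demonstrates correctness of the
pipeline and the *qualitative* robustness structure (fusion ≥ unimodal;
EMG degrades with noise faster than fusion; accuracy grows with channel
count), not the specific accuracies attainable on human recordings —
synthetic cohorts are more separable than real post-stroke data.

## Numerical and design choices

- "Overlap of 50 ms" is read literally (step = 200 ms); the alternative
  step = 50 ms is available via `WindowingConfig.step_ms`.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` substreams (per subject, pattern, repetition,
  modality, sweep cell); every generator is a pure function of
  (arguments, seed) and full sweeps are bit-identical under equal seeds.
- Degenerate inputs fail loudly: zero-length bone vectors, coincident chain
  points, windows shorter than 3 samples, classes with fewer rows than
  folds, misaligned fusion inputs, negative noise sd.
- Angles beyond [0, 180] produced by noise fold back through the geometry
  (a chain turned past straight re-measures as 360°−θ); templates keep
  their means far enough from the bounds that folding is negligible at
  default jitter.
- Problem sizes in the shipped tests: the stochastic study properties are
  averaged over ten cohort seeds of the full 10+5 default cohort; formula
  oracles use 1000 windows of 500 samples; the end-to-end determinism check
  runs a reduced demonstration configuration (2 normal + 1 post-stroke
  subjects, 3 repetitions) that exercises every stage.

## Known limitations

- Reported synthetic accuracies exceed those achievable on real subjects;
  only orderings and trends transfer.
- The planar-chain hand omits abduction/adduction, so poses differing only
  by finger spread are represented through small flexion differences.
- LDA assumes shared class covariance; the generator satisfies this only
  approximately (amplitude factors are multiplicative).
- Decision-fusion weights are fixed, not learned.
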