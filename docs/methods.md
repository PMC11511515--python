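# Methods

This note documents the models, estimators and design choices behind
`kinescore`, in the order the pipeline applies them, together with the
assumptions each step makes and the limitations we know about.

## Input model

A skeleton sequence is a uniformly sampled stream (fps > 0, spacing checked
to 1%) of 20 named 3D joint positions in meters, with per-joint tracking
validity. Joint numbering is resolved through a single canonical table
(`skeleton.CANONICAL_JOINT_MAP`); the shipped feature bank references
joints only through this table, so a different sensor layout requires
editing one file. Times are seconds from sequence start; all windows are
half-open [t₁, t₂) containing ⌊(t₂ − t₁)·fps⌋ samples. Short per-joint
tracking dropouts can be repaired by linear interpolation (`repair_gaps`);
runs longer than the caller's budget stay invalid and propagate as
per-cell invalidity, never as fabricated geometry.

## Feature bank

36 instantaneous features per frame: 26 angles (law of cosines at a vertex
joint, degrees in [0, 180]) and 10 NDDIs (normalized differences of two
inter-joint distances, in [−1, 1]). Both families are exactly invariant to
rigid motion and uniform scaling of the skeleton, which removes sensor
pose and body size from the analysis; the acceptance suite checks this
invariance to 1e-9. The bank ships as data
(`data/feature_bank.csv`), not code, and a hash of it travels inside every
model file; a model refuses to run under a different bank.

Angles with a zero-length arm and NDDIs with both distances zero are
undefined; the affected cell is marked invalid rather than given a value.
A window is unusable when any feature row has more than 10% invalid cells
(configurable); below that, invalid cells are dropped pairwise per
descriptor.

## Descriptors

Every unordered feature pair (630 = C(36,2), lexicographic order) yields:

* **CC** — Pearson correlation of the raw streams, in [−1, 1].
* **MI** — plug-in mutual information of the quantized streams, in bits.
  Angles are quantized into 18 ten-degree bins, NDDIs into 20 bins of 0.1;
  bins are left-closed/right-open except the last, which is closed so the
  range endpoints land in the top bin. Empty bins contribute 0 to entropy
  (0·log 0 = 0). The entropy base (2 by default) only rescales MI uniformly
  and cannot change any downstream ranking or argmax.

Numerical conventions:

* a constant stream has no linear-relation evidence: its CC is defined
  as 0 (flagged), keeping the vector complete and bounded;
* a stream whose sample standard deviation is below **half a quantization
  bin** (5° angular, 0.05 NDDI) is treated as *effectively* constant for
  CC purposes. This matters on real-style data: two nearly still features
  sharing a joint correlate through common sensor jitter, not through
  motion, and that jitter-driven "backbone" correlation is present in
  every window of every class. Zeroing sub-resolution streams removes it
  consistently from training profiles and test windows;
* plug-in MI is clamped at 0 against last-ulp negatives and satisfies
  0 ≤ MI ≤ min(H_i, H_j); the test suite checks it exactly against a
  brute-force double-loop histogram oracle.

MI is computed from sample histograms and is therefore blind to sample
order: phase shifts and moderate tempo changes of a periodic motion leave
the MI vector nearly unchanged (measured: < 0.01 bits mean per-component
drift for a 30% speed change, bound at 0.05 in the tests). This is the
property that lets windows be compared without dynamic time warping. The
flip side is that MI sees only *which features co-move*, not amplitudes,
frequencies or phase signs; limitations below.

## Descriptor selection

Per class, components are ranked by the discrimination index
DI = |mean_in − mean_out| / (std_in + std_out) (sample standard deviations,
ddof = 1; +∞ when both spreads vanish with distinct means, 0 when the means
coincide). Ties break toward the lower pair index, so selection is
deterministic. With the refinement filter off, the working set is literally
the top-n_D by DI.

The default refinement pass adds two requirements, both computed on
training data only:

1. **Distinctively high.** A candidate is deferred unless the class mean
   exceeds every training value observed outside the class. DI's absolute
   numerator would happily select components on which the class sits near
   *zero* (tiny spread → huge DI), but a near-zero signature g_q makes the
   unit-gain kernel below enormous in norm, and a component that other
   activities can drive to target level lets them overshoot the detector.
2. **Non-redundant.** A candidate whose within-class-centered training
   values correlate above 0.95 in absolute value with an already selected
   component is deferred: co-moving fluctuations mean the two components
   measure the same underlying joint relationship. Centering within class
   matters — raw pool correlations are dominated by the shared
   between-class pattern that *every* good discriminator exhibits.

Deferred candidates backfill in DI order if the pool runs out, so the set
always reaches n_D.

## Adaptive CEM detection

Class q's signature g_q is the mean of its training samples restricted to
K_q. The background matrix
R_q = (1/n_T) Σ_i (1/n_i) Σ_j x_{ij} x_{ij}ᵀ + B
weighs classes equally and samples within a class equally; B is the mean
outer product over the selected-descriptor vectors of the windows already
elapsed in the sequence being labeled (the discrete form of a time-averaged
integral; zero while nothing has elapsed). Elapsed windows are appended
*after* a window is labeled, so the context never contains the window under
test. The kernel H_q = R_q⁻¹ g_q / (g_qᵀ R_q⁻¹ g_q) satisfies g_qᵀH_q = 1
to 1e-8 and minimizes the mean squared background response subject to that
constraint (checked against an independent SLSQP solution). A ridge
λI, λ = 1e-6·tr(R)/n_D, is added only when cond(R) > 1e10, which covers the
near-singular cases that arise with small n_D early in a sequence.

Labeling rule per window: initial label = argmax of the responses (ties to
the lowest class id); confirmed only if the Pearson correlation between the
window's 630-component CC vector and the winning class's training CC
profile exceeds 0.5, else class 0 (unclassified). The confirmation
reference is the class mean CC vector by default; `confirm_mode="nearest"`
uses the maximum correlation over individual training samples instead
(both modes ship because either reading of "the training data representing
the winning label" is defensible; the mean is more stable in our
experiments, and the two were indistinguishable on the synthetic study).

Training descriptor conventions: per ground-truth segment, the MI vector
comes from the Δt window centered in the segment — matching the
histogram-bias regime of the inference windows — while the CC vector uses
the whole segment, since correlation estimates carry no length bias and the
longer stretch sharpens both confirmation profiles and scoring references.

Default parameters: Δt = 5 s, dt = 1 s, n_D = 2, 30 fps analysis rate, all
configurable (`PipelineConfig`). Lower frame rates (10/6/4.3 fps) are
reached by integer-stride decimation (stride = round(native/target)), which
avoids resampling artifacts. dt may go as low as one frame interval; the
1 s default keeps a 60 s sequence at 56 windows.

## Scoring

Per class the references are the mean CC vector of the perfect-scored
(100) executions, *b*, plus the individual imperfect executions (w_m,
S_m < 100). A vector x projects onto each line b→w_m; the line with the
smallest perpendicular distance v wins (ties to the lower index), and with
d the signed projection length and D = ‖w_m − b‖:

    score = 100                                if d < 0
          = max(0, 100 − (d/D)(100 − S_m))     otherwise

i.e. 100 at b, S_m at w_m, linear in between and beyond, clamped at 0.
This is the unique continuous piecewise-linear rule consistent with
"simple linear interpolation" plus the boundary statements that a negative
projection scores 100; the source's printed casework for this formula is
typographically corrupted, so the continuous reading is a documented
interpretation, not a transcription.

When only a subset of m imperfect references is used (the 1→3 reference
study), references are picked at evenly spaced positions of the
score-sorted candidate list, anchored at the worst execution — a growing
set covers the coach-score range as evenly as possible, emulating the
collection of additional scored training samples.

Only windows lying fully inside a single labeled exercise segment are
scored; mixed windows get a reason code instead of a number, since their CC
content belongs to no single activity.

## Synthetic study

The generator builds 20-joint skeletons by forward kinematics on a
fixed-bone-length rig (exact bone-length invariance is tested), driven by
15 rotation channels (shoulder abduction/flexion, elbows, hip
abduction/flexion, knees, 3-DoF spine) plus a vertical pelvis bob. Nine
exercise programs — jumping jacks, squats, toe-touch kicks, windmills,
biceps curls, overhead press, side bends, high knees, toe touches — are
sums of sinusoids on subsets of these channels. The programs were designed
so that each class has a pair of feature groups that co-moves for it alone;
this is a *requirement* of co-movement descriptors, not a convenience (see
limitations).

Per execution: tempo factor ~ U(0.85, 1.15), global phase ~ U(0, 2π), and a
coach score q ∈ [0, 100] drawn from the ladder 100, 100, 95, …, 60 across
the repetitions of a class (one guaranteed perfect reference plus a spread
of imperfect ones). A deficit δ = 100 − q degrades execution three ways:
amplitude multiplier 1 − 0.0045δ; slow Ornstein–Uhlenbeck form drift on
every active channel (std 0.3 + 0.9·√δ degrees, timescale 2 s — "losing the
form", not frame noise); and a systematic timing fault, alternate channels
leading/lagging by 0.011·√δ turns. The √δ scaling makes independent small
faults accumulate linearly in variance, so the CC displacement grows
roughly linearly with the deficit and the linear scoring geometry is the
right model for it. The ground-truth score is q itself, so scoring accuracy
is unambiguous. All joints carry 8 mm isotropic Gaussian noise emulating
depth-skeleton jitter.

Background (non-exercise) time models a person idling between sets: 0.8°
OU postural sway on every channel plus Poisson gesture bursts (~one per
6 s, 1–3 channels, raised-cosine envelope, up to ~45°). Sequences place an
execution between background spans with a 0.5 s raised-cosine blend just
outside the labeled segment.

Default study scale, chosen to emulate the shape of a realistic protocol
while running in tens of seconds: 9 classes × 10 repetitions, 60 s per
execution at 30 fps, 30% background time, evaluated on an independently
generated session. What passing this study shows — and what it does not —
is spelled out under limitations.

## Evaluation

Window-level comparison at the prediction's grid, with class 0 as a
first-class label; the ground truth of a window is the class covering the
majority of it (uncovered time counts as background, ties to the lower
id). Overall accuracy and Cohen's kappa come from scikit-learn and are
pinned against hand-coded textbook formulas in the tests; score regression
uses ordinary least squares of predicted on true scores (slope, R²) plus
the RMSE of the raw residuals. The sweep harness trains and evaluates once
per cell of the adjusting-parameter grid (window length {5, 7, 10, 15,
20} s × rate {30, 10, 6, 4.3} fps × n_D {2, 4, 8, 12, 20} = 100 cells by
default) in deterministic Cartesian order. When a whole recorded session
is evaluated, its sequences are labeled with a shared background buffer, as
one continuous stream — resetting the adaptive context per sequence leaves
it cold at every sequence start.

## Known limitations

* **Amplitude blindness.** MI and CC are invariant to the amplitude of a
  motion. A half-depth squat performed rhythmically looks like a full
  squat to the descriptors; amplitude errors are only visible through
  nonlinear leakage and through the drift/timing faults that accompany
  them in realistic executions. The synthetic quality model therefore
  carries its score signal mainly in timing and form drift, and a scoring
  deployment on real data should expect the same bias.
* **Subset degeneracy.** A class whose moving-feature set is contained in
  another class's (e.g. plain lateral raises vs. jumping jacks) has no
  descriptor component that is uniquely high for it, and its unit-gain
  detector can be overshot by the superset activity. The exercise
  vocabulary must be chosen with distinct co-movement patterns; the
  shipped programs are.
* **Axial rotations are nearly invisible** to this feature bank: angles
  measured against near-vertical reference directions are unchanged by
  rotation about the vertical axis, so pure torso twists barely register.
* **Slow coordinated background motion** can imitate the CC profile of
  slow, spine-driven exercises; the >0.5 confirmation is the only gate for
  windows that win the argmax with weak responses, and it is the main
  source of residual background false positives in the synthetic study.
* The plug-in MI estimator is biased upward at small window lengths; the
  pipeline matches training and inference window lengths for MI instead
  of correcting the bias.
* The simulator does not model occlusions (validity is all-true by
  default), soft-tissue or anthropometric variation, depth-dependent
  noise, or human raters' scoring noise; passing its study demonstrates
  the machinery end to end under controlled conditions, not field
  performance on sensor data.
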