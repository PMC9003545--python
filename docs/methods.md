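# Methods

This note documents the models, conventions and numerical choices behind
`reachval`, in the order the pipeline applies them.

## Coordinate and unit conventions

All positions are in millimetres in a lab frame with +X anterior (toward
the target), +Y to the participant's left, +Z vertical up; time is in
seconds. The marker set is the seven-point upper-body set a depth-camera
skeleton exposes: hand (first metacarpal / wrist joint), elbow, assessed
and contralateral shoulder, trunk (manubrium / spine-shoulder), and both
hips (corrected to the hip-joint centres upstream). Recordings are stored
as tidy long CSV; device dropouts encoded as NaN runs are repaired by
linear interpolation up to 0.2 s, longer gaps reject the trial.

## Temporal and spatial alignment

The two sensors are synchronized by the lag that maximizes the normalized
cross-correlation of their hand-speed profiles (searched within ±1 s; an
error is raised if either series is flat or the best correlation is below
0.3, meaning there is no movement to align on). Spatial alignment is the
closed-form least-squares rigid fit (SVD of the cross-covariance of the
centred clouds; if the unconstrained optimum is a reflection the smallest
singular direction is sign-flipped, so a proper rotation is always
returned). The correspondence set pools all time-aligned samples of the
shoulder, trunk and hip markers — the slow-moving, least artifact-prone
points — rather than a calibration pose; one transform is fitted per
trial pair (a per-session mode would only require caching the transform).

A deliberate property of the downstream variable battery is that it is
almost invariant to a *consistent* rigid misalignment: displacements are
norms, joint angles are measured in body-local frames, and retained angles
difference out constant offsets. Alignment still matters for anything
sample-wise (time-series RMSE, shared segment bounds, plots), which is why
it stays in the default path.

## Filtering and spectra

Positions are low-pass filtered per axis with a 2nd-order Butterworth
applied forward and backward (zero net phase; effective gain is the
squared single-pass magnitude, i.e. 0.5 at the cut-off). The default
cut-off is 2.5 Hz; the `band_power_fraction` helper verifies the
justifying criterion that ≥ 95% of the periodogram power of natural reach
trajectories lies below it. Edge transients are handled by reflective
("even") padding of length 3 · order · f_s / f_c samples (capped at the
series length); series shorter than 15 samples are rejected rather than
padded. The 30 Hz markerless stream is filtered at its native rate before
any resampling, so artifact energy is attenuated where it lives.
Differentiation is central differences (one-sided at the edges).

## Reach segmentation

Segmentation lives entirely in the 1-D task space d(t) = ‖hand(t) −
target‖. Multi-reach trials are first split at local maxima of d separated
by ≥ 0.5 s (prominence ≥ 20% of the distance range); a window counts as a
reach only if d drops below 30% of the starting distance. Within a window,
with v = −ḋ (positive while approaching):

* **t_final** — the protocol rule "when the distance reached its
  minimum" is implemented as the *earliest local minimizer of d within a
  tolerance band* (1% of the approach depth) of the global minimum, with
  the strict arg-min as fallback. On a reach-and-hold movement d bottoms
  into a near-flat band; the strict first global minimizer lands wherever
  noise or filter ripple happens to be smallest — an unstable and biased
  estimate — whereas the banded rule returns the moment the hand first
  settles, is stable to ±2 samples under 0.5 mm sensor noise, and still
  picks the end of the second submovement when a reach genuinely pauses
  short of the target on the way.
* **t_peak** — first maximizer of v before t_final (ties break earliest).
* **t₀** — one sample after the last non-positive v at or before t_peak
  (window start if v is positive throughout); a peak at the window edge
  raises a truncation error.

Zero-phase filtering smears movement onset and settling symmetrically, so
t₀ and t_final each carry an irreducible bias of roughly 0.02–0.04 s at
the 2.5 Hz cut-off, independent of movement amplitude. Timing variables
are therefore accurate to about ±0.05 s absolute, not to a percentage;
amplitude variables (velocities, displacements, ratios) recover analytic
ground truth within ~2% in the noise-free limit.

## Kinematic variables

Anatomical angle constructions (the variables are standard, the
constructions are this package's):

* **Elbow angle**: angle at the elbow between (shoulder − elbow) and
  (hand − elbow); 180° = full extension.
* **Trunk anterior flexion**: signed angle of the mid-hip→manubrium axis
  from lab vertical, in the sagittal X–Z plane, positive forward.
* **Trunk rotation**: signed transverse-plane angle of the shoulder line
  relative to its orientation at the first sample, positive when the
  assessed-side shoulder advances.
* **Shoulder flexion / abduction**: the humerus vector expressed in a
  per-sample trunk frame (longitudinal = mid-hip→manubrium; medio-lateral
  = hip line orthogonalized; anterior completes the right-handed triad);
  flexion is the sagittal-plane angle from the downward longitudinal axis
  (positive forward), abduction the frontal-plane analogue (positive away
  from the trunk). An arm hanging along the trunk scores 0/0.

All five are reported as retained angles: value at t_final minus value at
t₀. Hand metrics over [t₀, t_final]: movement time; path length ratio
(travelled path / straight-line start-to-end distance); peak and mean of
the 3-D speed; time from t₀ to the speed maximum; and the number of
velocity peaks, counted with a prominence threshold of 5% of the peak
speed (an unthresholded count is noise-dominated; the fraction is
configurable). Displacements are net (not path) start-to-end norms.
PAU = 100 (Δhand − Δtrunk)/Δhand is computed per reach and averaged over
the five reaches of a condition before the PANU subtraction; the non-use
flag fires above 6.5 percentage points.

## Agreement statistics

The observation unit is the pooled reach pair (subject × condition ×
reach) for per-reach variables, the condition for PAU and the subject for
PANU; a `pooling="subject"` option averages within subject × condition
first. Reaches are matched across sensors by segment-midpoint proximity
(greedy one-to-one within 1 s), so a spurious artifact-window on one
sensor cannot shift the correspondence of later reaches.

Statistics per variable: one-way random-effects single-rating ICC from the
explicit ANOVA decomposition (this form penalizes systematic offsets,
unlike consistency-type two-way ICCs); squared Pearson r; RMSE with the
gold sensor as truth; NRMSE = 100 · RMSE / range(gold); Bland–Altman bias
= mean(test − gold) with 95% limits of agreement bias ± 1.96 · sample SD;
and relative systematic error 100 · (mean_test − mean_gold)/mean_gold.
The sign convention makes overestimation by the test sensor positive
everywhere. Labels: Koo–Li bands for ICC (lower edges closed, ≥ 0.9
excellent) and the complementary 10/25/50% cut-offs on |relative error|
for validity. Degenerate variables (zero variance, zero range, zero gold
mean) yield NA rows with a reason instead of aborting the report.

## Synthetic data generator

The generator emulates the validation protocol — n subjects × 2 trunk-use
conditions × 5 reach-and-return cycles toward a fixed target 300 mm from
the starting hand position, recorded by a 100 Hz gold sensor and a 30 Hz
markerless sensor — with closed-form ground truth for every variable.

**Movement model.** Hand progress along a (possibly laterally bowed) path
follows a minimum-jerk profile; trunk marker and both shoulders translate
forward by `trunk_gain` × progress (hips fixed), so Δtrunk = gain · D and
PAU = 100(1 − gain) exactly; the elbow comes from two-segment arm inverse
kinematics (upper arm 300 mm, forearm+hand 380 mm, elbow biased down and
outward). Per-reach smoothness variation: with probability 0.4 a reach
undershoots by 25–50 mm and corrects with an overlapped minimum-jerk
submovement (0.45 s, starting at 95% of the primary movement) — the
standard corrective-submovement model, producing a second velocity peak
that survives 2.5 Hz filtering. Smooth and corrective reaches of a subject
take the same total time (a speed–accuracy/isochrony choice), so
smoothness and movement duration vary independently — without this the
raw-data noise-peak counts of both sensors co-vary through shared segment
duration and reliability comparisons confound the two factors. Subject
heterogeneity: reach duration uniform 0.9–1.3 s; trunk gains 0.25
(spontaneous) / 0.05 (restrained) with N(0, 0.04) per-subject×condition
jitter (clipped to [0, 0.9]) so PAU/PANU have real between-subject
variance; per-trial path bow uniform 0–35 mm. A `load_condition` flag
scales duration ×1.3 and trunk gain ×2 to emulate loaded (stroke-like)
reaching without modelling dynamics.

**Sensor models.** Gold: linear resampling to 100 Hz plus 0.2 mm white
Gaussian position noise (the magnitude of a marker system's static error,
modelled white for simplicity). Markerless: resampling to 30 Hz; transient
"armrest confusion" artifacts — Poisson-timed events (0.5 s⁻¹ on the hand,
double on the elbow, emulating elbow occlusion) that displace the marker
60 mm toward a fixed distractor behind the resting hand with 0.1 s
exponential recovery; 3 mm white noise; and finally the inverse of the
device-to-lab transform (10° rotation about the medio-lateral axis plus a
translation), so the stream arrives in an oblique device frame as a real
mounting would deliver it. All randomness flows from one seed through a
splittable seed sequence; identical seeds give byte-identical datasets.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: soft-tissue artifact, marker occlusion on the
gold system, autocorrelated or depth-dependent markerless noise, skeleton
bone-length re-estimation jumps, lens distortion, dropped frames, and any
true biomechanical coupling between trunk and arm beyond the kinematic
translation model. Synthetic agreement numbers characterize the pipeline,
not the device.

## Problem sizes and runtime

The test suite and the acceptance script use desk-scale sizes chosen to
keep a full run in well under a minute on one CPU: 20 subjects (400 paired
reaches) for the study-level checks, 1000 random paired datasets (N =
5–50) for the statistics-layer oracle equivalence, 100 random rigid
motions for alignment recovery, and 3 noise levels × 3 replicate seeds ×
6 subjects for the monotone-degradation property.

## Known limitations

* Timing landmarks inherit the ±0.02–0.04 s zero-phase filter bias
  discussed above; comparisons between sensors are unaffected (both carry
  it), but absolute movement times are shortened by about 2%.
* The trunk-rotation variable on synthetic data has near-zero true
  variance (the generator's compensation is translational), so its ICC is
  uninformative there — consistent with the variable's poor reliability
  on real depth-camera data, but for a different reason.
* The one-way ICC is undefined when total variance is zero and strongly
  negative under large offsets with small spread; NA rows and negative
  values are reported as computed, not clamped.
* The PAU formula is the displacement-share definition; it is isolated in
  a single function so an alternative operationalization can be swapped in
  without touching the pipeline.
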