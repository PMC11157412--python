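# Methods notes

This note documents the models, parameter choices and numerical
conventions behind each analysis stage, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Coordinate conventions and sign of rotation

Pose tables arrive in image coordinates (x right, y down). All angular
quantities are reported with "clockwise as seen from above = positive",
which for a mouse filmed from above means turning toward its right side.
In y-down image coordinates a clockwise on-screen rotation has a positive
planar cross product, so no axis flip is needed for standard video; tracks
with y-up coordinates set `PoseTrack.y_down = False` and the sign is
flipped internally. The convention is asserted by a reflection test:
mirroring the coordinates flips the sign of angular velocity.

## Calibration

The pixel-to-centimeter scale is the known marker spacing divided by the
median pixel distance between consecutive calibration markers, the median
taken across frames where both markers are tracked with likelihood ≥ 0.8.
The median makes the scale robust to occasional marker mis-detections.
Corridor views use four dots 5 cm apart; the open field uses the four
arena corners 40 cm apart.

## Stimulation-epoch detection

The stimulation train is encoded by a small LED in the field of view that
receives a copy of the train. The LED is only detectable by the pose
estimator while lit, so its likelihood trace is the on/off signal; the
threshold reuses the 0.8 likelihood cutoff. A 20 Hz pulse train flickers
at a 50 ms inter-pulse interval, so supra-threshold runs separated by less
than `merge_gap_s` = 0.2 s are merged into one epoch and merged runs
shorter than `min_on_s` = 0.5 s are discarded. Detection depends only on
the likelihood series, never on the LED's position.

## Quality control

Exclusion rules, evaluated per landmark-frame on raw (unsmoothed)
coordinates so that a second application is a no-op:

| rule | threshold | rationale |
|---|---|---|
| likelihood | < 0.8 | estimator's own confidence |
| out_of_arena | outside corner-marker convex hull | physically impossible |
| body_speed | > 334 cm/s | fastest locomotor speed recorded in mice |
| part_speed | > 400 cm/s | body-speed cap + 20 % margin for limb segments |
| joint_gap | adjacent joints > 2.3 cm apart | tibia length in wild-type mice |

Arena containment uses the convex hull of the median corner positions
with zero tolerance. The body-speed rule excludes the body center and the
tail base at the offending frames; the joint-gap rule excludes the distal
joint of the offending pair. Static scene landmarks (corners, calibration
dots, LED) are exempt. Masked frames propagate as gaps downstream:
derivative computations bridge gaps of ≤ 2 frames by linear interpolation
and split the trace at longer gaps, which prevents one bad detection from
producing a spurious speed spike.

Speed for rule evaluation is deliberately unsmoothed; smoothing happens
downstream in the analysis stages. Whether the original exclusion rules
used smoothed or raw speed is not documented anywhere we know of; raw is
the stricter choice.

## Speed and locomotion bouts

Speed is the frame-to-frame body-center displacement over elapsed time
(timestamps when available, else 1/fps), then a centered 5-frame moving
average — the same window established for paw speeds, adopted for the
body center as well.

Locomotion/immobility segmentation uses hysteresis: locomotion starts
when speed stays ≥ `speed_on` = 3 cm/s for ≥ 0.5 s and ends when it stays
< `speed_off` = 1 cm/s for ≥ 0.5 s. These three numbers are conventions
of this package (common field practice), not measured constants: bout
counts depend on them, so every bout summary records the thresholds used,
and they are exposed in the configuration.

## Angular kinematics

Angular velocity: the body-orientation vector runs from the tail base to
the body center. For two consecutive frames, the unique circle tangent to
both orientation vectors at the body-center positions subtends at its
center exactly the angle between the two vectors, so the implementation
computes the signed successive-vector angle directly and multiplies by
fps; the tangent-circle picture is kept as the geometric justification
and cross-checked against the v/R closed form on circular trajectories.

The body-orientation angle α is the arena-frame angle of the vector from
the tail base to the midpoint of the inter-ear line. It is unwrapped over
time before baseline subtraction so that multi-revolution turns accumulate
past ±180°, then normalized by subtracting its mean over the 0.5 s
preceding stimulation onset. The head-rotation angle β is the signed angle
between the body axis and the perpendicular of the inter-ear vector, the
perpendicular chosen to point rostrally (within 90° of the body axis);
same baseline normalization. Frames with coincident ears or zero-length
body axis are flagged and skipped.

## Gait cycles

Joint angles are interior angles of the labeled chain, in (0, 180]; they
are invariant under rigid motion and uniform scaling, which the suite
asserts. Stance/swing segmentation follows the asymmetric rule as
specified: a lift-off needs ≥ 14 consecutive frames above 15 cm/s of
5-frame-smoothed MTP speed; the touchdown is the first frame back at or
below threshold, with no minimum run. Cycle normalization resamples each
touchdown-to-touchdown segment onto 101 points (0–100 %, the standard
grid in gait analysis) by linear interpolation; cycles containing a
masked gap are dropped and counted rather than interpolated. Excursion
comparisons use per-animal amplitudes (max − min of the animal's mean
profile) and the parametric/non-parametric gate below.

## Limb-pair phase and motor arrest

The alternation distance d is the left-minus-right paw position projected
on the corridor length axis (principal axis of the calibration-marker
line; straight-line travel is assumed, lateral displacement discarded).
The mapping of distance to phase needs a normalization constant that no
published rule fixes; this package uses the 95th percentile of |d| over
pre-stimulus locomotion (falling back to the whole trial), clipped, which
is robust to outlier splays. The constant is recorded in every output so
results can be re-normalized.

Arrest/resume detection: the phase is smoothed with a 10-frame moving
average; the per-frame variation |Δφ| is compared strictly against
0.1°/frame; an arrest (resume) is the first frame after light onset
(offset) that *begins* a run of ≥ 20 contiguous qualifying frames. The
alternative anchor (last frame of the run) shifts latencies by a constant
and is available as `run_anchor = "end"`. On noise-free simulated gait
the recovery error is bounded by the smoothing lag (10 frames = 33 ms at
300 fps), which the suite asserts.

The 0.1°/frame threshold is strict: with realistic per-frame Gaussian
landmark jitter (σ = 1 px) the smoothed variation rarely stays below it
for 20 consecutive frames, so arrest detection in practice requires the
near-noiseless plateaus that real frozen limbs produce (pose-estimator
noise on a stationary high-contrast target is far below per-frame
i.i.d. pixel noise). The suite therefore tests detection latencies on
noise-free simulations and tests phase values (e.g. the arrest-to-resume
phase difference) under jitter.

Step-cycle continuity compares phase slope signs before arrest and after
resume, anchored at extrema of prominence ≥ 60°: ascending must resume
ascending, except when the phase froze at an extremum, where the slope
must switch. "At an extremum" is operationalized as the frozen value
lying within 5 % of the trace amplitude of an extremum level of the
surrounding cycles — the frozen plateau itself can register as a local
extremum and is excluded from this comparison. One documented consequence
of the prominence rule: when the arrest freezes the phase close below a
just-passed extremum and the resumed movement recrosses that extremum's
level, the extremum's prominence collapses below 60° and the slope anchor
falls back to the preceding extremum; the enumerated truth table in the
test suite records the resulting labels.

## Dose-response fits

Laser powers are normalized per animal to % of maximum and binned into
right-closed 5 % bins; the fit runs on the per-bin means (per-trial
fitting is available). The sigmoid family is a four-parameter logistic
with free bottom and top; a three-parameter variant (bottom pinned to the
pre-stimulus mean) can be emulated by fixing `bottom`. Initialization is
multi-start with x0 seeded at each quartile of the binned x, best final
SSE wins; non-convergence from every start returns a diagnostic-carrying
result instead of raising. R is defined as √(1 − SSres/SStot) to match
the reporting convention of common nonlinear-regression packages (R²
conventions differ for nonlinear fits, hence the explicit definition);
the p value comes from the regression F statistic, and the 95 %
confidence band is the pointwise delta-method band from the parameter
covariance. R is invariant under affine rescaling of the response, which
the suite asserts.

## Fiber optics

The light cone in tissue has full divergence 2·arcsin(NA/n); with
NA = 0.22 and n = 1.36 this is 18.6°. Irradiance attenuation combines
conical geometric spread with scattering:

    ρ = r·√((n/NA)² − 1),   T(z) = ρ² / ((S·z + 1)·(z + ρ)²),

normalized so T(0) = 1. The scattering coefficient default
S = 11.2 mm⁻¹ (mouse brain near 473 nm) follows the widely used
brain-tissue irradiance calculator; with the 200 µm-core, 0.22-NA fiber
defaults, 98.8 % of irradiance is lost 1 mm from the tip. The model is
monotone decreasing in depth and is not a radiative-transport simulation.

## Statistical test gate

Two-group comparisons choose their test from the data: Shapiro-Wilk
normality on the paired differences selects paired t versus Wilcoxon
signed-rank; for independent groups, normality of both samples plus a
Levene equal-variance test selects pooled t, Welch t, or Mann-Whitney.
All tests are two-sided with α = 0.05. Identical paired samples are
reported as t = 0, p = 1 rather than an error.

## Cell-count aggregation

Per-animal rows (possibly several slices per animal) are summed per
animal first; the per-animal percentage is 100·pos/denom. The default
summary is the arithmetic mean of per-animal percentages, with the pooled
percentage (100·Σpos/Σdenom) always reported alongside, because the two
diverge when denominators differ across animals; the pooled value always
lies within the per-animal range. Display rounding is half-away-from-zero
to one decimal. For some marker pairs in the bundled counts the two
methods bracket, but neither reproduces, previously printed percentages;
the module reports both and asserts neither.

## The synthetic-data generator

The generator emulates the study's recording conditions: a 40 × 40 cm
open field at 30 fps with 10-s stimulation trains every 80 s over a
15-min session (`default_openfield_config`), and 300-fps corridor passes
with 5 cm calibration dots, a trot-like gait, and programmable motor
arrests (`default_corridor_config`: one 2-s train with arrest latency
330 ms and resume latency 1100 ms — the evoked-arrest regime). Gait
defaults are 4 strides/s with a 7 cm stride and 35 % swing fraction
(body speed 28 cm/s, a brisk mouse walk); joint-angle waveforms are
sinusoids with field-plausible means and amplitudes (hip 120 ± 15°, knee
120 ± 30°, ankle 110 ± 25°, MTP 140 ± 20°) driven through a 2-D
forward-kinematic chain whose segment lengths all sit below the 2.3 cm
QC cap. Body geometry constants (tail base 3 cm behind the body center,
ears ± 1 cm about a point 1.5 cm ahead) are invented and configurable.

Arrests freeze all body landmarks through a warped gait clock that stops
advancing during the arrest window, so movement resumes in the phase
where it stopped (matching arrests captured in stance; an
"at-next-stance" option defers the freeze to the next touchdown). The
noise model is isotropic Gaussian pixel jitter plus Bernoulli dropout
frames carrying a configurable low likelihood — the two dominant failure
modes of markerless pose estimation. Same seed and configuration produce
byte-identical output.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: autocorrelated tracking error, occlusions,
identity swaps, lens distortion, perspective foreshortening, variable
stride timing, postural sway during immobility, or a corridor traversal
that turns around (the simulated pass is a single straight run, so very
long noiseless runs can exceed the nominal corridor length). Estimator
accuracy on real video is bounded below by these effects.

## Test problem sizes

Simulated recordings in the suite are seconds long (2–30 s) rather than
full 15-min sessions, with trial counts of 3–10; these sizes are chosen
so each estimator sees several cycles, bouts or trials of the feature it
measures, which is sufficient because every property asserted is either
exact or has an analytically bounded error that does not shrink with
longer recordings.
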