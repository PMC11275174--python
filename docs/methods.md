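# Methods

## System model

The package models a body sensor network of nine six-axis IMUs at fixed
wear positions (left/right forearm, left/right upper arm, waist, left/right
thigh, left/right calf), each reporting 3-axis acceleration and 3-axis
angular rate on a 0.2 s tick.  Recognition of the three motion states rests
on a single physiological observation: the number of body segments in
vigorous motion is ordered across activities — essentially none while
standing, the six gait-driving limb segments (forearms, thighs, calves)
while walking, and all nine while jumping.  The pipeline therefore reduces
each window of data to one integer, the active-sensor count, and thresholds
it.

### Units

Acceleration is treated as a dimensionless raw sensor quantity everywhere.
The activity bands the classifier relies on span roughly 20–25,000, which is
the scale of unconverted 16-bit MEMS accelerometer counts, not of m/s²; no
full-scale/LSB calibration is available to map them to physical units, and
none is needed because the classifier is scale-free once the threshold is
expressed in the same units.  Angular rate is radians per second in memory;
the CSV dialect converts from degrees per second (the default on disk).

## Attitude solution

A complementary quaternion filter of the Mahony family. Per sample:

1. normalise the accelerometer vector (the norm is computed once from the
   raw components before any division);
2. predict body-frame gravity from the quaternion,
   `v = (2(q1q3 − q0q2), 2(q0q1 + q2q3), q0² − q1² − q2² + q3²)` — the third
   row of the body-to-world rotation matrix;
3. error `e = â × v`, whose magnitude is proportional to the tilt drift;
4. integral state `eInt += Ki·e`; corrected rates `g = ω + Kp·e + eInt`;
5. first-order quaternion update with `halfT` (half the sampling period);
6. re-normalisation.

Step 6 is an addition to the written update: a first-order step inflates
the norm by O((|g|·dt)²) per sample, and the gravity prediction and Euler
extraction both assume unit norm, so without it the filter drifts off the
unit sphere within a few hundred steps.  Yaw and roll are extracted with
the two-argument arctangent (a single-argument arctan is ambiguous by π);
the pitch arcsine argument is clamped to [−1, 1] against floating-point
overshoot at the gimbal poles.

**Defaults** `Kp = 2.0`, `Ki = 0.005`, `halfT = dt/2`: conventional
magnitudes for this filter family, giving a gravity-correction time
constant of a few tenths of a second at solver rates while letting the
integral term absorb slow gyro bias.  All three are exposed
(`fusion.kp/ki/half_t`).  A zero-norm accelerometer sample (free fall — an
expected instant during jumps) skips the correction branch and falls back to
pure gyro integration rather than erroring the stream.

Coordinate conventions: right-handed axes with Z up at rest; scalar-first
quaternions; intrinsic Z-Y-X Euler angles (yaw, pitch, roll).  Without a
magnetometer, yaw is observable only through gyro integration and drifts
with gyro noise; roll and pitch are anchored by gravity.

## Kalman smoothing

The written filtering stage specifies the generic predict/update recursion
but not its state vector or matrices.  The package's declared choice is the
simplest model consistent with "smooth the fused data": each acceleration
channel is an independent scalar random walk observed in white noise
(A = H = 1, B = 0).  `Q = 0.01·R` by default; `R` is estimated from the
sample variance of the first 10 samples of the channel (streams are assumed
to start at rest, so early scatter is measurement noise).  The covariance
update is propagated in Joseph form, which is algebraically identical to
`(I − KH)P⁻` at the exact gain but remains positive semi-definite under
round-off.  The scalar steady state has the closed form
`P⁻ = (Q + √(Q² + 4QR))/2`, `K = P⁻/(P⁻ + R)`, used as the oracle in tests.

Whether the original filtering stage acts on quaternions, Euler angles or
accelerations is unspecified; since the classifier consumes accelerations,
this package filters accelerations, and the stage can be bypassed with
`kalman.enabled: false`.

## Threshold classifier

Per window: rectify each sample (`V_k = |a_k|`), mark a site active when any
axis strictly exceeds `A` (boundary equality is inactive — activation is
"greater than"), count distinct active sites `i`, and label
walk for `I₁ ≤ i ≤ I₂`, jump for `i ≥ I₃`, stand otherwise (the gap
`I₂ < i < I₃`, reachable only for non-default bounds, also falls to stand,
keeping the three predicates exhaustive and mutually exclusive).

The source system describes an accumulate-until-quiet cycle whose exact
extent is ambiguous; the package's declared reading is fixed-length
non-overlapping windows of `threshold.window` ticks (default 1, i.e. one
decision per 0.2 s), with the window length configurable to emulate longer
cycles.  A site missing from a window counts as inactive and the decision
records which sites were observed — graceful degradation for dropped
packets.  A trailing partial window is classified from the ticks it has.

**Defaults** `A = 1000`, `I₁ = 3`, `I₂ = 6`, `I₃ = 7`.  The activity bands
only constrain the ordering, not the values: any `A` strictly between the
standing maximum (200) and the walking minimum (2000) separates the
noiseless bands perfectly (property-tested across that interval), and 1000
sits in the geometric middle.  `I₂ = 6` matches the six gait limbs,
`I₃ = 7` requires at least one additional segment, and `I₁ = 3` tolerates
up to three missing/quiet limbs while walking.  All four are calibration
parameters (`threshold.a/i1/i2/i3`).

## Synthetic data

`generate_activity_stream` draws per-axis rectified magnitudes uniformly
inside the per-activity bands — standing [20, 200] on all nine sites;
walking [2000, 5000] and [5000, 10000] on the six limb sites, the two
sub-bands alternating between the left and right limb groups on successive
ticks to mimic gait asymmetry, trunk sites staying in the standing band;
jumping [9000, 25000] on all nine sites.  Uniform draws are the maximum-
entropy choice given that only ranges are known.  Signs are random per
sample; the classifier rectifies, so they carry no label information.
Optional Gaussian jitter (`noise_sd`) is clipped back into the band, so
band containment is exact by construction.  A *confusable* mode injects
boundary events (trunk swing into 9000–10,000 during walking, trunk dropout
during jumping, limb twitches while standing) to produce off-diagonal
confusion qualitatively, without claiming any particular error rate.

What this emulates — and what it does not: the generator reproduces the
band structure, the active-site sets and the tick interval of real
recordings, but not biomechanical waveforms, inter-axis correlation,
temporal autocorrelation within a segment, or person-to-person variation.
Passing tests therefore demonstrate that the decision logic is correct and
that the bands are separable as published, not that the accuracy figures
would transfer to new human data.  In particular, because signs are drawn
independently per sample, the synthetic signal is zero-mean at high
frequency, and pre-rectification smoothing would wash its magnitudes out;
the simulated recognition experiment therefore thresholds the generated
magnitudes directly, while the CLI pipeline keeps smoothing on by default
for field data.

`generate_imu_trajectory` produces attitude ground truth: body-frame
angular rates from the analytic intrinsic Z-Y-X kinematics
(`ωx = ṙ − ẏ·sin p`, `ωy = ṗ·cos r + ẏ·cos p·sin r`,
`ωz = ẏ·cos p·cos r − ṗ·sin r`), accelerometer readings equal to the true
body-frame gravity direction (computed via scipy's rotation classes, an
implementation independent of the filter under test) scaled by a
configurable magnitude, plus Gaussian channel noise.  Trajectory fixtures
default to `dt = 0.02 s`: attitude solvers conventionally run an order of
magnitude faster than the 0.2 s storage tick, and at 0.2 s a first-order
integrator cannot hold unobservable yaw drift under a degree for realistic
gyro noise.

## Evaluation

Rates are `100·diag/total` per class; reporting is at two decimals with
half-up rounding; the class-mean is taken over the *unrounded* per-class
rates and then rounded.  Pooled accuracy (trace/total) is computed
separately and never substituted for the class-mean.  When scoring
simulated trials, one schedule segment is one trial and the trial's
prediction is the majority window label, ties resolved toward stand (then
walk): counting is per trial, and majority voting is the declared bridge
from window decisions to trial outcomes.

Problem sizes used by the test suite and the reproduction script: 1000
trials per class for the recognition experiment, 10⁵ steps for the
quaternion-norm soak, 10⁴ cycles for covariance stability, 10⁴ samples for
smoother variance.

## Known limitations

- No magnetometer: yaw is unanchored and drifts with gyro bias/noise.
- The scalar random-walk smoother is a declared simplification; correlated
  multi-axis models are out of scope.
- Raw-unit thresholds mean `A` must be recalibrated for any sensor with a
  different full-scale configuration.
- The synthetic generator's independence assumptions (above) make its
  accuracy figures an upper bound on real-data performance.
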