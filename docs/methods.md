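# Methods

This note documents the models, the numerical choices, and — because the
package ships its own reference-free test bed — exactly what the synthetic
data do and do not emulate.

## Orientation estimation

The attitude of the sensor is a scalar-last unit quaternion q = (q1, q2, q3,
q4) for the sensor-to-navigation rotation; `quat_to_dcm` returns the
navigation-to-sensor direction-cosine matrix C_ns, so the predicted gravity
direction in the sensor frame is the third column of C_ns. The Mahony
complementary filter corrects the gyro rates with e = â_s x ĝ_s (both
unit-normalized, so the error magnitude is scale-invariant and bounded by 1)
through a PI law with gains K_p and K_i. The quaternion propagates with the
first-order update matrix q' = (I + Δt/2 Ω(ω)) q followed by explicit
renormalization, which bounds the linearization error; over 10^5 steps the
norm stays within 1e-9 of 1.

Parameters (all in `PipelineConfig.mahony`):

* `kp = 2.0` (1/s). Proportional gain; sets the accelerometer-attraction
  time constant (~1/K_p) and the steady tilt error under gyro bias
  (bias/K_p).
* `ki = 0.05` (1/s^2). Integral gain; the bias-absorption pole sits at
  K_i/K_p, i.e. a ~40 s time constant. A much smaller K_i leaves a
  0.01 rad/s gyro bias essentially uncompensated within a 20 s trial, whose
  gravity leak (~0.05 m/s^2) is the margin the static-convergence check
  runs at; 0.05 keeps that leak near 0.035 m/s^2 with a comfortable margin
  while remaining in the conventional Mahony range.
* `acc_gate_tol = 0.10`. The correction is applied only when the measured
  specific-force magnitude is within 10% of g. During running swing the
  foot sees tens of m/s^2 of kinematic acceleration; an ungated gain-2
  correction would drag the attitude toward a meaningless "gravity"
  direction. Gating restricts corrections to stance — exactly where the
  accelerometer is informative — and is standard practice in foot-mounted
  inertial navigation. Setting the tolerance to infinity disables the gate.
  Near-zero specific force (free fall, dropout) always skips the
  correction.

The initial attitude is the zero-yaw rotation taking the mean stationary
acceleration (samples with gyro norm strictly below 0.0436 rad/s) onto +z.
The orientation filter consumes unfiltered samples; the 6 Hz event filter
is applied downstream only.

## Event detection

All event detectors operate on zero-phase (forward-backward) 4th-order
Butterworth 6 Hz low-passed signals; zero-phase filtering is what makes the
detected timestamps unbiased — a symmetric pulse keeps its extremum in
place, at the price of squaring the single-pass attenuation.

* Mid-swing: positive local maxima of filtered ω_x above
  mean + `k_sigma`·SD (k_sigma = 1), with an absolute floor
  (`min_peak_rads` = 1 rad/s) so stationary recordings yield "no strides"
  rather than noise-peak segmentation; peaks deduplicated within
  `min_separation_s` = 0.4 s (running stride times are 0.6–1.0 s), keeping
  the larger amplitude, ties to the earlier peak.
* Conventional IC: `avgs_convention` selects the classic negative peak
  (default) or the zero-crossing refinement. The negative peak is searched
  in the first `negpeak_frac` = 0.5 of the stride; the toe-off dip always
  lies beyond the first half of a stride window, the foot-strike dip always
  inside it, so 0.5 separates the two events across the plausible
  duty-factor range (0.33–0.48).
* Fused IC: kinematic candidate = the positive-to-non-positive zero
  crossing of ω_x nearest the coarse estimate inside a window of
  `window_frac` = 0.3 of the stride centred on it; kinetic candidate = the
  |a_ap| maximum in that window (sign-agnostic, so rearfoot and forefoot
  braking both trigger); IC = `w_acc`·t_kinetic + (1−`w_acc`)·t_kinematic
  with `w_acc` = 0.7. Missing candidates degrade gracefully (kinetic-only,
  then coarse) with flags.
* Fused TC: forward window (`search_lo_frac`, `search_hi_frac`) = (0.1,
  0.6) of the stride after IC, bracketing plausible running contact times
  (CT/ST ≈ 0.3–0.5); kinematic candidate = zero crossing of the second
  difference of ω_x nearest the window's angular-velocity minimum (the
  conventional toe-off dip); kinetic candidate = the signed positive
  (propulsive) a_ap maximum. The conventional TC is the dip minimum itself;
  defining it inside the forward window rather than "after mid-stance"
  avoids a circular dependency, since mid-stance detection needs the stance
  interval.
* Mid-stance: stance trimmed by `trim_frac` = 0.1 at both ends, window
  `window_frac` = 0.3 of stance slid one sample at a time; gyro-energy and
  horizontal-variance minima blended by
  w = σ²_a / (σ²_a + |σ²_a − σ²_a,prev|), clamped to [0, 1], first stride
  w = 1 (the printed form without the absolute value can exceed 1 or
  divide by ~0). Horizontal means navigation-frame x, y — a world-frame
  notion. Exact ties in the window minima break to the earliest window.
  Sub-sample timestamps stay float seconds; conversions to sample indices
  round half-up.

The fusion weights are not identifiable from first principles; 0.7/0.3 is
the package default for "dominant accelerometer weight" and is fully
config-exposed.

## Stride reconstruction

ZUPT integration runs MS-to-MS: mid-stance is the only instant where the
zero-velocity assumption is physically valid. (Integration between
mid-swing points is available behind `reconstruction.anchor = "msw"` for
comparison.) Velocity is the cumulative trapezoid of the unfiltered
gravity-compensated acceleration — the 6 Hz event filter would distort
displacement amplitude (`filter_before_integration` exposes the
alternative). Drift correction subtracts w_j = j/n times the endpoint
velocity per axis: exact zero at both anchors, exact annihilation of any
drift linear in time (hence of any constant acceleration bias, e.g. a
steady gravity leak), idempotent. Only zero *velocity* is enforced at the
anchors; a zero-acceleration assumption is not enforceable on measured
data. Stride length is the horizontal resultant, invariant to heading.

## Parameters

FT = (SWT − CT)/2 is the single-foot flight-time estimate under left-right
symmetry; with typical running values (SWT 0.432 s, CT 0.308 s) it gives
0.062 s, in the physiological range, whereas the alternative reading
SWT − CT/2 = 0.278 s is not a running flight time — this arithmetic pins
the formula down. Negative FT (walking-like input) is reported with a
`no_flight` flag but clipped to zero inside the force model to keep it
physical. The spring-mass vGRF is the half-sine
F(t) = (π/2) m g (FT/CT + 1) sin(π t/CT); the argument π t/CT is the only
dimensionally consistent reading that vanishes at both stance ends. Its
stance impulse is m g (CT + FT): body weight supported over the full step,
the SLIP impulse balance. F_max = (π/2)(FT/CT + 1) in body weights,
strictly increasing in FT/CT.

## Agreement statistics

Differences are always reference − estimate. Limits of agreement are
bias ± 1.96·SD (sample SD, n−1); the bias CI uses 1.96·SE, not a
t-quantile. ICC is the two-way mixed *consistency* form from the ANOVA
mean squares; both ICC(3,1) and ICC(3,k) are reported because the two
conventions label single-rating and mean-of-k forms inconsistently across
the literature, and the choice matters (Spearman-Brown: ICC(3,k) ≥
ICC(3,1) whenever between-subject variance dominates). Shapiro-Wilk
normality is reported informationally and never gates an analysis.
`paired_t_and_cohens_d` returns (0, 1, 0) for identical series; a nonzero
constant difference (zero variance) is an error.

## Synthetic gait generator

The generator emulates over-ground running recorded by an instep-mounted
IMU at 200 Hz. Defaults are the validated operating range of comfortable
self-selected running: stride time 0.74 s, contact time 0.308 s, stride
length 1.93 m (≈2.6 m/s), mass 75.2 kg, mounting tilt 8°, accelerometer
noise σ = 0.3 m/s², gyro noise σ = 0.01 rad/s, constant gyro bias
0.005 rad/s (consumer-IMU order of magnitude). A 2 s stationary lead-in
initializes the orientation filter.

Trajectory conventions (and their rationale):

* Forward motion is ramp-plateau-ramp per stride: Hann-shaped propulsive
  and braking acceleration lobes centred exactly on TC and IC. A symmetric
  lobe's extremum survives zero-phase filtering in place, so the kinetic
  event markers are unbiased by construction. The plateau speed is
  stride_length/swing_time, so mid-stance-to-mid-stance displacement is
  exactly one stride length.
* Sagittal pitch rate is a wide mid-swing lobe (peak `peak_pitch_rate`,
  default 8 rad/s, at the exact swing midpoint), a heel-rise/toe-off dip
  around TC, a late-swing positive pedestal, and a foot-strike dip whose
  *onset* pins the zero-crossing marker and whose *minimum* is the
  conventional negative-peak IC. Lobe areas are balanced (the toe-off dip
  amplitude is solved from the others) so the foot returns to flat every
  stride. A rearfoot strike centres the foot-strike dip just after IC
  (foot-slap); a forefoot strike attenuates it (amplitude ratio 0.625/1.25
  of the mid-swing peak), advances it to 0.08 swing-durations before IC,
  and slightly advances the braking-acceleration peak — reproducing the
  early-trigger bias of conventional angular-velocity detection that the
  fused detector is designed to remove. True event times are identical
  across strike patterns.
* Vertical motion is a raised-sine lift (default 0.10 m) over the swing.
* Ground-truth IC/TC are also expressed in the force-plate convention (25 N
  threshold crossings of the modelled vGRF), which sit ~2 ms inside the
  nominal stance.

What the simulator does **not** emulate: soft-tissue artifact, sensor
mounting wobble, treadmill dynamics, speed drift within a trial,
medio-lateral foot motion, and any stance-phase rotation outside the
landing/push transients. Because the push-off and landing transients
straddle the stance edges (as real ones do), the gyro is exactly quiet only
over the central ~50–60% of stance — which is the region mid-stance
detection and ZUPT actually rely on — rather than over the whole of it.
Passing tests therefore demonstrate correct mechanics of the pipeline and
its documented failure-mode ordering (fused beats conventional on forefoot
strikes), not performance on real tissue-borne signals.

## Problem sizes and determinism

Simulated checks use 10–12 strides per trial, a 15-runner x 3-trial cohort
for recovery, a 10-runner forefoot cohort for the method comparison, and
200 random profiles for the ordering sweep; these sizes give hundreds of
strides per statistic while keeping the whole suite in the tens of
seconds. All simulation randomness flows from a single seed; the analysis
path contains no randomness, so identical input and config give
byte-identical outputs. Estimated and reference strides are paired by
nearest IC within a 50 ms gate (a force-plate-targeting protocol is not
available to a simulator), and unmatched strides are dropped with a
warning.

## Known limitations

* The fused IC inherits 30% of the zero-crossing's earliness; on forefoot
  signals its residual bias is ~10–15 ms (vs ~40–60 ms conventional), not
  zero.
* Heading is unobservable without a magnetometer; stride length is
  heading-invariant by construction, but 3-D trajectories are not
  produced.
* The spring-mass vGRF is a half-sine template: peak estimates track
  FT/CT, not the true loading waveform; real impact transients are absent
  by design.
* Agreement statistics require variation across strides/trials; on a
  single constant-parameter trial, correlation-type statistics are
  undefined and are reported as errors rather than numbers.
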