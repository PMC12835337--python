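# runstride

Running-gait analysis from a single foot-mounted IMU.

Wearable inertial sensors make gait analysis possible outside the motion-capture
laboratory, but everything downstream — stride length, contact time, ground
reaction force — hinges on detecting the gait events precisely. Conventional
rule-based detection reads initial contact (IC) and terminal contact (TC)
straight off extrema of the sagittal angular velocity; its timing drifts with
running speed and shifts systematically earlier as the strike pattern moves
from rearfoot to forefoot. `runstride` implements a multi-sensor fused,
stride-adaptive event detector alongside that conventional angular-velocity
baseline, reconstructs stride kinematics with zero-velocity updates, estimates
kinetics with a spring-mass model, and ships the agreement statistics used to
validate such systems — plus a synthetic foot-IMU simulator with exact ground
truth, so the whole pipeline is testable end to end without laboratory data.

Intended users: biomechanics and sports-science researchers or engineers
working with foot-mounted IMUs (instep mounting, tri-axial accelerometer +
gyroscope, ~200 Hz).

## Method

**Orientation.** A Mahony complementary filter tracks the sensor attitude
quaternion q. The gravity direction predicted from q is compared with the
normalized measured specific force through a cross product, e = â_s x ĝ_s,
which feeds a proportional-integral correction of the gyro rates
(ω_corr = ω + K_p e + K_i ∫e dt); the integral term absorbs constant gyro
bias. Gravity-compensated navigation-frame acceleration follows as
a_n = C_ns(q)ᵀ a_s − g_n.

**Events.** Strides are segmented at mid-swing (MSW): positive peaks of the
6 Hz zero-phase-filtered sagittal angular velocity ω_x above an adaptive
threshold mean + k·SD. Within each stride:

* IC — the conventional estimate (negative peak of ω_x, or its
  positive-to-non-positive zero-crossing refinement) seeds a search window of
  30% of the stride; the fused estimate is a weighted combination of the
  zero-crossing (kinematic marker) and the braking peak of anterior-posterior
  acceleration (kinetic marker), with the dominant weight (0.7 by default) on
  the accelerometer.
* TC — fused analogously from the angular-velocity inflection near the
  toe-off dip and the propulsive acceleration peak inside a forward window
  (10–60% of the stride after IC).
* MS (mid-stance) — inside the trimmed stance (first/last 10% excluded), a
  sliding window of 30% of stance locates the minima of tri-axial gyro energy
  (t_ω) and horizontal acceleration variance (t_v); they are blended with a
  variance-continuity weight w = σ²_a / (σ²_a + |σ²_a − σ²_a,prev|).

**Strides.** Navigation-frame acceleration is integrated MS-to-MS with zero
initial velocity (ZUPT); the endpoint velocity error is removed linearly
(w_j = j/n), enforcing zero velocity at both anchors; a second integration
gives displacement and stride length SL = sqrt(d_x² + d_y²).

**Parameters.** Per stride: ST = t_IC,i+1 − t_IC,i; CT = t_TC − t_IC;
SWT = ST − CT; FT = (SWT − CT)/2 (single-foot symmetry estimate);
SF = 120/ST steps/min; SV = SL/ST; and a spring-mass (SLIP) vertical GRF
F(t) = (π/2) m g (FT/CT + 1) sin(π t/CT), whose peak in body weights is
F_max = (π/2)(FT/CT + 1).

**Validation statistics.** Bland–Altman bias and limits of agreement,
Pearson's r, two-way mixed consistency ICC(3,1)/ICC(3,k), MAE, 1.96·SE
confidence intervals, paired t-tests and Cohen's d.

## Worked example

```python
from runstride import GaitProfile, simulate_run, analyze, PipelineConfig
from runstride.pipeline import compare

rec, truth = simulate_run(GaitProfile(seed=7))       # ~12 s of running at 200 Hz
res = analyze(rec, PipelineConfig(mass_kg=75.2))
print(res.summary().to_string(index=False))
```

```
   parameter       mean       sd  n
          sv   2.610956 0.004981 10
          sl   1.932115 0.003680 10
          sf 162.161501 0.005605 10
          st   0.740003 0.000026 10
          ct   0.308576 0.000019 10
         swt   0.431427 0.000023 10
          ft   0.061426 0.000017 10
peak_vgrf_bw   1.883483 0.000102 10
```

The simulated runner has stride time 0.74 s, contact time 0.308 s and stride
length 1.93 m; the pipeline recovers them to well under 1 ms / 1% (SV in m/s,
SL in m, SF in steps/min, times in s, peak force in body weights). Comparing
both detectors against the generator's truth:

```python
rep = compare(rec, truth.params)
```

```
CT error (truth - estimate), fused:        -0.0006 +- 0.0000 s
CT error (truth - estimate), conventional: +0.0080 +- 0.0000 s
```

On forefoot-strike profiles the gap widens sharply (tens of milliseconds of
conventional bias), which is the failure mode the fused detector targets.

The same pipeline runs from a shell:

```bash
runstride simulate --seed 7 --out-dir out/
runstride analyze out/synthetic.csv --out-dir out/ --mass-kg 75.2
runstride compare out/synthetic.csv out/synthetic_truth.json --out out/cmp.json
runstride validate out/ref_params.csv out/est_params.csv --out out/agreement.json
```

Recordings are CSV (`time,ax,ay,az,gx,gy,gz`; declare units in the config if
they are g / deg/s); configuration is a JSON or YAML file validated against
the schema in `runstride.config`.

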