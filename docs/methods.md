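# Methods

`imugait` reconstructs lower-limb joint kinematics of walking and stair
climbing from seven body-worn inertial measurement units (pelvis/L5, both
thighs, shanks and feet; accelerometer ±6 g, gyroscope ±2000 °/s,
magnetometer ±8.1 G, 128 Hz) and computes the clinical outcome metrics used
in pre/post-treatment studies of knee osteoarthritis: joint range of motion
(ROM), angular speed range (SPEED), stride time, cadence, timed-walk speed
and 6-min distance, together with paired statistics and test-retest
reliability (ICC, SEM).  Because no raw recordings of the motivating study
are publicly available, the package ships a synthetic-data module that
forward-simulates the full sensor stack from known joint kinematics; every
processing stage is validated by recovery against that known truth.

## Orientation estimation

Each sensor's orientation (sensor → world, world frame Z up along gravity,
X along the horizontal component of the magnetic field) is estimated by a
gradient-corrected complementary filter: gyroscope body rates are
integrated with the exact quaternion exponential and corrected toward the
accelerometer gravity direction and the magnetometer heading with a single
scalar gain (default 0.1 s⁻¹).  Two standard safeguards keep linear
acceleration from tilting the estimate: the tilt correction weight falls
linearly to zero as |‖a‖ − 1 g| approaches 0.1 g, and it is further scaled
down with gyro magnitude (vanishing above 100 °/s), so the accelerometer is
trusted mostly in the quieter phases of the cycle.  The magnetometer only
corrects the component of error about the vertical axis (heading), so
magnetic disturbance cannot corrupt tilt.  The initial orientation comes
from the mean accelerometer and magnetometer over the first second; a
free-fall window (accelerometer near zero) is a hard error.  Gyroscope bias
is estimated as the mean rate over the first detected static interval, with
10% of the interval trimmed at each edge so that movement onset bleeding
into the detection cannot masquerade as bias.

## Sensor-to-segment calibration

Anatomical segment frames are X anterior, Y left, Z up in quiet standing.
Calibration is functional, from a walking bout plus a standing interval:

* **Vertical axis** — mean accelerometer direction while standing (gravity).
* **Hinge QC** — the principal direction of the walking gyroscope signal,
  weighted by squared rate magnitude to emphasize swing.  If it carries less
  than 0.6 of the gyro variance the movement is not hinge-like enough and
  the calibration is rejected with an error; the fraction is reported as
  the per-segment QC score.
* **Medio-lateral axis azimuth** — with Z pinned by gravity and Y forced
  orthogonal to it, the only remaining freedom is the azimuth of Y.  The
  gyro principal axis is an asymptotically biased azimuth estimator on
  rigid chains (the coupling ω_x ≈ flexion rate × axial tilt correlates
  with the flexion rate itself, tilting the principal axis by several
  degrees), so the azimuth is instead taken from the straight-walking
  constraint: the time-averaged medio-lateral direction over the bout is
  horizontal and perpendicular to the progression heading.  The principal
  axis is still compared against this direction and a deviation above 30°
  is logged.  This hybrid keeps the functional (movement-derived) character
  of the calibration while removing its azimuth bias; in simulation it cuts
  the aligned-mounting calibration error from 4–8° to ≈1°.
* **Pelvis** — the pelvis rotates too little and too isotropically for any
  principal-axis rule; its anterior axis is taken from the estimated
  heading while standing, under the assumption that the subject stands
  facing the direction of progression.

Both rules assume progression along the magnetic-horizontal world X axis;
this is the documented operating assumption of the calibration, satisfied
by construction in the synthetic sessions.

Joint angles are the relative rotation of the calibrated distal segment in
the calibrated proximal frame, decomposed with the mobile
flexion → ab/adduction → axial-rotation sequence (intrinsic Y–X–Z in the
axis layout above, sagittal sign flipped so flexion is positive forward);
pelvis angles are segment-to-world.  Samples with |frontal angle| > 85° are
flagged for gimbal proximity.  Angular velocity is the central finite
difference of the raw angle series ((x[k+1] − x[k−1])·fs/2, one-sided at the
ends).  No low-pass filter is applied before differentiation by default; a
zero-phase 4th-order filter frequency can be configured (`lowpass_hz`) and
is logged when used.

## Segmentation and events

Task bouts are found by flat-zone/peak thresholds on the accelerometers:
static intervals of the pelvis sensor (gyro norm < 5 °/s, accel norm within
0.05 g of 1 g, runs ≥ 0.5 s after closing sub-0.1 s noise gaps) partition
the recording, and an inter-flat span counts as a bout when a shank
accelerometer shows step peaks at ≥ 0.4 Hz.  Bouts are labeled in the
configured task order.

Initial contacts are peaks of the world-vertical shank acceleration above
median + 3·MAD (capped at 60% of the span's peak amplitude so very dynamic
stair bouts keep their heel-strike candidates), at least 0.4 s apart,
gated by the joint kinematics at contact: the hip sagittal angle must be
within 30% of its local-window maximum and the knee must be extending.  A
second adaptive pass drops candidates below 35% of the typical candidate
height.  Foot-off events are out of scope.

Cycles run from one contact to the next same-side contact.  The metrics use
the three consecutive cycles whose durations deviate least (summed absolute
deviation) from the median cycle duration, with mid-bout preference on
ties; each selected cycle is linearly resampled onto 101 points (0–100% of
the cycle, endpoints inclusive) and averaged pointwise.  ROM and SPEED are
max − min of the averaged angle and angular-velocity cycles; SPEED is
computed by differentiating the raw series first and normalizing the
velocity cycles, not by differentiating the averaged angle cycle.  Stride
time is the mean inter-contact interval (both sides pooled), cadence is
60/stride time in cycles per minute — reported table columns elsewhere
label this "step/min" while their stride-time counterparts imply
cycles/min (1.20 s ↔ 50.7); this package reports cycles/min throughout and
does not rescale.  Timed-walk speed is track length / bout duration; the
6-min distance is taken from the pedometer-equivalent ground-truth distance
in synthetic mode.

## Statistics

Pre/post comparisons: Shapiro–Wilk on the paired differences at α = 0.05
routes each metric to the two-tailed paired t-test (normal) or the Wilcoxon
signed-rank test (non-normal; zero differences dropped, exact p for n ≤ 25
without ties, else a continuity-corrected normal approximation).  Constant
difference vectors, for which Shapiro–Wilk is undefined, go to the Wilcoxon
branch.  No multiple-testing correction is applied by default (α = 0.05 per
metric, mirroring the original analysis); Holm adjustment is available.

Reliability: two-way mixed-model, single-measure, consistency ICC,
ICC = (MS_subjects − MS_error)/(MS_subjects + (k−1)·MS_error) with the
subject × trial interaction as error, so a constant between-trial offset
does not lower it.  Single-measure (not average-measure) is used because
SEM columns are on the single-trial scale.  SEM = SD·√(1 − ICC) with SD
pooled over both trials; √MS_error is available as an alternative
(`sem_formula="ms_error"`).  Duplicated trials return ICC = 1 and SEM = 0
exactly; zero between-subject variance flags the ICC as undefined.

## Synthetic data

The generator produces ground-truth joint angles as sums of at most three
cycle-locked harmonics per joint and plane, normalized on a dense grid so
the continuous curve's range is exactly twice the requested amplitude.
Default amplitudes, stride times and speeds are seeded from published group
summaries (patients pre/post and healthy reference).  The phase structure
is physiological where it matters to the pipeline: peak hip flexion falls
at initial contact, the knee is near extension and extending at contact
with its flexion peak at ~70% of the cycle, and out-of-sagittal waveforms
alternate sign down the chain the way pelvis obliquity/rotation and hip
ab/adduction counter-phase in gait, which keeps each limb segment's
rotation sagittally dominated as real segments are.  The left side lags by
half a cycle (configurable) and mirrors the frontal/transverse signs.
Bouts are framed by standing lead-in/lead-out with 0.4 s raised-cosine
transition ramps; true initial contacts sit at the cycle boundaries
(n_cycles + 1 per side, the left side's last contact landing inside the
lead-out).

A rigid chain (pelvis width 0.24 m, hip drop 0.10 m, thigh and shank
0.40 m, foot 0.15 m, sensors at mid-segment with small anterior offsets)
converts angles to segment orientations and sensor positions; the pelvis
translates at the task's progression speed with a 1.5 cm vertical bob.
Sensors measure: gyroscope = interval-mean body rates of the sensor frame
(+ constant per-sensor bias drawn U(−b, b) + white noise); accelerometer =
rotated specific force (gravity + double-finite-difference linear
acceleration, in g) + white noise; magnetometer = rotated Earth field
(unit norm, 60° inclination, horizontal component along world X) + noise;
all channels clipped at the hardware full scales.  Two non-idealities are
modeled explicitly: a soft-tissue wobble of the sensor on its segment
(sinusoidal rotation, default 0.5° at 6 Hz, scaled by the segment's own
angular speed so it vanishes in standing) and a damped heel-strike
transient (1.5 g Gaussian-windowed 16 Hz burst on the shank and foot
accelerometers, peaking exactly at each true contact) — without the latter
a smooth harmonic chain would contain no impact content for the event
detector to find.  Default white-noise levels (accel 0.02 g, gyro 0.4 °/s,
bias 0.5 °/s, mag 0.05 G) are typical of consumer MEMS parts.

Cohorts: each subject draws one truncated (±1.75 SD) standardized factor
per movement plane, applied multiplicatively to all joints of that plane
(between-subject ROM variation is strongly correlated along the kinematic
chain; per-plane pooled CVs come from the published SDs), plus stride-time
and speed factors (stride CV capped at a physiological 12% — the published
healthy stride SD of 0.69 s on a 1.15 s mean is outlier-inflated).  Draws
are additionally conditioned on the limb segments remaining sagittally
dominated (analytic medio-lateral rate fraction ≥ 0.65, redrawn otherwise):
a cohort on which walking functional calibration is ill-posed could not
have produced the published tables.  Treatment effects shift the post
ground truth by the published mean differences with per-subject SDs implied
by the printed p-values (sd_d = |diff|·√n / t⁻¹(p); this reproduces the few
printed diff SDs well), truncated at ±1.75 SD and clipped into the
published post-treatment marginal range.  Test-retest pairs share the
subject's ground truth exactly; trials differ in sensor noise and re-donned
mounting rotations (random axis, |N(0, 3°)| by default).  Consequently the
temporal metrics (stride time, cadence, timed speeds) are perfectly
repeatable across trials and their ICC/SEM are degenerate at 1/0; only the
angle-based metrics carry measurement error into the reliability table.

What the simulator does **not** emulate: ground contact mechanics and
ground-reaction forces (feet do not obey a floor constraint), magnetic
disturbance, turning in the 6-min walk (simulated as a short representative
bout whose sidecar carries the ground-truth total distance), stair
geometry (stair tasks reuse the harmonic machinery with stair amplitudes),
within-subject stride-to-stride biological variability beyond optional
timing jitter, and OA pathology beyond metric shifts.  Passing recovery
tests therefore demonstrates the correctness of the processing chain on
rigid-body-consistent signals with realistic sensor error, not performance
on real skin-mounted recordings.

## Problem sizes and numerical choices

The demo study uses the published cohort sizes (14 pre/post patients, 12
healthy test-retest pairs), all five tasks with 6 cycles per bout, ≈60 s
and ≈7900 samples per session; recovery studies use 10-cycle walks.  All
randomness flows from one seed through `numpy.random.default_rng` with
per-subject/per-session spawned integers below 2³¹, and the demo rerun is
byte-identical under a fixed seed.  Quaternions are kept hemisphere-
continuous by sign flips; the orientation integrator uses the closed-form
quaternion exponential; event indices are integers on the 128 Hz grid;
report CSVs are written with 10 significant digits.

## Known limitations

The heading-based azimuth rule assumes straight-line progression during the
calibration bout.  SPEED estimates inherit differentiation noise (tens of
°/s with the default noise model) because no filter is applied before the
finite difference by default.  The ICC of temporal metrics in the synthetic
reliability table is exactly 1 by construction (see above).  Stair
kinematics are summary-matched, not biomechanically modeled.
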