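# Methods

## Scope and model

`gstride` reconstructs foot kinematics from a single foot-mounted IMU by
zero-velocity-aided strapdown inertial navigation, derives a per-stride
and per-walk gait-parameter set, and fits logistic fall-risk models
(univariate cut-offs, multivariable models, repeated-split evaluation) on
a participant cohort table. Because the package must be verifiable
without any recording, it ships forward generators for both inputs; their
defaults define the reference conditions every test and experiment runs
under.

## Synthetic walk generator

The foot alternates motionless stance dwells and swings on a straight,
level line. Within a gait cycle of duration GCT the four phases occupy
configurable fractions (defaults: loading 0.11, foot-flat 0.42, pushing
0.18, swing 0.29 - values typical of slow older-adult gait and matching
the stance-dominated split reported for this population). Position is
pinned during the whole stance; the swing advances one stride length with
a minimum-jerk quintic profile (zero velocity and acceleration at both
ends) and lifts the foot on a C2 polynomial bump whose apex is the
commanded clearance. Pitch ramps from the heel-strike angle (default
+15.6 deg, toes up) to flat during loading, stays flat during foot-flat,
ramps to the toe-off angle (default -53.9 deg, toes down) during pushing,
and returns during swing. Ramps use smoothstep interpolation rather than
straight lines: a C1 pitch profile keeps the angular-rate signal free of
jumps, so midpoint-rule orientation integration at 100 Hz does not leak
gravity into the horizontal channel; every commanded landmark (pitch
extremum at heel-strike/toe-off, apex clearance, phase boundaries) is
preserved exactly.

From the analytic trajectory the generator emits exact specific force
(`f_b = R(pitch)^T (a_w - g_w)`) and angular rate, plus additive white
noise. Defaults: 100 Hz sample rate, accelerometer SD 0.05 m/s^2, gyro SD
0.005 rad/s - representative of consumer MEMS parts; the device class
this emulates publishes no sensor specs, so these are the package's own
reference conditions. Frames: world X forward / Y left / Z up; sensor
axes coincide at zero pitch; pitch positive toes-up, so heel-strike
angles are positive and toe-off angles negative.

Ground truth returned with each recording: the stance schedule (the n
zero-motion foot-flat dwells - during loading and pushing the foot pivots
in place, so a ZUPT detector keyed on gyro quietness must not claim
them), per-stride event times, and the true trajectory arrays. A walk of
n commanded strides contains n+1 stance dwells (a lead-in standing dwell
plus one per stride) and therefore n-1 complete heel-strike-to-heel-strike
cycles.

### What the generator does not emulate

Real recordings contain turns, stops, stairs, sensor bias and bias
instability, mounting misalignment, soft-tissue wobble, and
stride-to-stride physiological variability; the generator has none of
these (its only stochasticity is white sensor noise). Passing the
recovery tests therefore demonstrates the correctness of the
detection/integration/segmentation contracts, not field accuracy on
pathological gait.

## Stance detection and reconstruction

A sample is stance when |(specific-force magnitude) - g| < 0.4 m/s^2 and
the gyro magnitude < 0.6 rad/s, with runs shorter than 0.1 s discarded;
all three thresholds are exposed. Initial attitude comes from
accelerometer levelling over the first stance (minimal rotation aligning
the mean specific force with vertical; yaw is unobservable and irrelevant
to per-stride quantities). Orientation integrates midpoint-rule rotation
increments forward and backward from that anchor; pitch is re-anchored at
every stance by levelling, with the correction interpolated linearly
between stance midpoints. Velocity integrates the gravity-compensated
world-frame specific force (cumulative Simpson); the ZUPT correction
zeroes it during each stance run and removes a linear-in-time drift ramp
across each swing, anchored on the per-stance mean velocities; position
integrates the corrected velocity. An error-state Kalman filter would
admit richer noise models, but on the contract surface here (per-stride
lengths and angles between stance anchors) stance-anchored de-trending is
the equivalent fixed-interval-smoothed solution, so it is the single
implementation. Gravity defaults to 9.81 m/s^2, configurable. A
recording with no stance run raises a "no ZUPT anchor" error rather than
returning a drifting solution; non-finite states name the failing sample.

## Event detection and parameters

Toe-strike and heel-off bound the pitch-quiet run (|pitch rate| < 30
deg/s, minimum 0.05 s) inside each stance; toe-off is the pitch minimum
between a heel-off and the next toe-strike, heel-strike the pitch maximum
after it - the contact angles are read at exactly those samples, matching
their definition as the pitch extrema at the events. When no quiet run
exists (foot-flat-free gait) the foot-flat collapses to the single
quietest sample, so loading+pushing absorb the stance share and the
foot-flat share reports ~0, with a logged warning; when the pitch range
in a search window is below 2 deg (flat-pitch input) events fall back to
the stance-interval edges.

Stride length is the horizontal distance between the mean positions of
consecutive stance runs; clearance is referenced to the ground level of
the stance preceding the swing (robust to slow vertical drift); the 2D/3D
paths sum position increments across the cycle, which guarantees
path3d >= path2d >= SL. Phase percentages are event-interval ratios, so
they sum to 100 identically. Step speed is SL/GCT by definition.

Per-walk summaries report totals plus the mean and STD of each stride
parameter. Conventions, each exposed as a parameter: steps = 2 x strides
(one instrumented foot, contralateral steps inferred by symmetry);
cadence = per-stride steps/GCT averaged over strides; walk velocity =
total distance / total recording time, which includes stance dwells and
therefore sits below step speed; STDs use the population estimator
(sample optional). Segmentation emits only complete cycles; an optional
trim drops the first and last complete cycle for field recordings with
start/stop transients, and stays off by default because simulated walks
have clean boundaries.

## Cohort generator

Participants are drawn per group (faller / non-faller) with independent
per-variable Gaussians; ordinal scales (GDS 1-7, SPPB components and
total, FES-I) are rounded and clipped to their ranges, binary traits are
Bernoulli. Demographics follow the published descriptives of the cohort
this emulates (fallers older, shorter, more often female); all other
defaults are synthetic-only values placing each group midpoint near the
corresponding published univariate cut-off with roughly 0.8-1 SD group
separation - the effect size the study's own power analysis assumed. A
single `effect_scale` dial shrinks or stretches all group differences.
Because features are independent within groups, the joint separability of
the default cohort exceeds a real cohort's (correlated predictors carry
less combined information): multivariable accuracies on synthetic data
are upper bounds, and the tested claims are therefore directions,
cut-off locations and procedural identities, never published accuracy
values. An optional logistic label model replaces group-membership labels
for parameter-recovery experiments.

## Risk models

All fits are maximum-likelihood logistic regressions (statsmodels Logit).
Choices the source material leaves open, resolved as follows:

* **Cut-off definition**: the probability-0.5 crossing,
  `-intercept/slope`. This reproduces the published walk-speed row
  (3.68/4.33 = 0.8499 ~ 0.849 m/s) exactly; a few other published rows
  deviate from their own printed coefficients beyond rounding, which is
  left as an inconsistency of the source rather than resolved by another
  definition.
* **Separation**: the MLE diverges under complete separation, so the fit
  falls back to a weakly ridge-penalized IRLS solution (alpha = 1e-3) and
  flags the result; the decision boundary stays finite and sign-stable,
  and the Wald statistics are marked indicative.
* **Confidence intervals**: Wald on the log-odds scale.
* **Splits**: unstratified simple random sampling, test size
  `round(0.3 n)` (49 of 163); the nominal product `repeats x 0.3 x n`
  (2445 at the study size) is reported alongside the realized count.
  Single-class training draws are redrawn and logged, never skipped.
* **Averaging**: confusion counts averaged over repeats, statistics
  derived from the averaged matrix (per-repeat-statistic averaging is an
  option); AUC is the rank/Mann-Whitney statistic averaged per repeat.
* **Undefined ratios** (zero denominators) are NaN, never 0.
* **Multiple testing**: none is applied to the cut-off table, mirroring
  the descriptive use of those p-values; consumers needing inference
  across ~45 variables must correct externally.
* **Degenerate report inputs**: a single-class cohort yields one empty
  probability histogram rather than an error; constant variables are
  rejected with a message naming them, as are rank-deficient designs.

## Problem sizes

Validation experiments are sized for precise estimates at interactive
runtimes: the stride-length experiment uses 6 walks x 36 commanded
strides (210 measured strides, ~4 min of simulated walking); recovery
grids use ~10 strides per cell; cohort experiments use n = 163 (the study
size) to 5000 (parameter recovery at 3-SE tolerance). The full test
suite runs in a few seconds on one core.

## Known limitations

Straight-line, level-ground model only: no turning detection, terrain,
left/right asymmetry (single sensor), magnetometer or barometer fusion.
Sensor errors are white noise only - no bias states, so long-recording
drift behaviour beyond the per-stride horizon is not modelled. The
cohort generator's independence assumption is stated above. Follow-up
(prospective fall) outcomes are out of scope; the label is retrospective
faller status.
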