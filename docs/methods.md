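# Methods

This note documents the estimation pipeline, the synthetic gait model used
to validate it, the numerical and design choices that were genuinely open,
and the limits of what the validation shows.

## Estimation pipeline

### Signals and frames

Each foot-mounted IMU reports specific force (m/s², sensor frame; a level
stationary sensor reads (0, 0, +g) with g = 9.80665 m/s²) and angular
velocity (deg/s). The global frame is z-up. Quaternions are Hamilton,
scalar-first, encoding the sensor-to-global rotation. Heading (yaw) is
unobservable without a magnetometer; it is initialised to zero per trace
and every reported quantity is constructed to be heading-invariant.

### Quiet-standing calibration

The window defaults to the first 2 s, auto-shrunk to the longest prefix
whose gyro norm stays below the swing threshold; it must be at least 1 s.
The gravity direction is the normalised mean accelerometer vector; the gyro
bias is the mean gyro vector, subtracted from the whole trace before any
further processing. With gyro noise of 0.5 deg/s and a 2 s window, the
residual bias is ≈ 0.03 deg/s per axis; the tilt components of that
residual are continuously corrected by the orientation filter, while the
yaw component drifts (see *Step metrics* below for why this is harmless).

### Role of the low-pass filter

The 4th-order, 4 Hz zero-phase Butterworth removes sensor noise and impact
ringing for *event detection*: phase segmentation and coarse heel-strike
localisation run on the filtered signals. Orientation propagation and the
double integration deliberately consume the bias-corrected **raw** signals
instead. A zero-phase low-pass at 4 Hz (its magnitude response applies
twice) attenuates the heel-strike rotation pulse severalfold and smears the
swing's velocity pulse symmetrically into the adjacent stances; velocity
that leaks into a stance is then zeroed by the zero-velocity update and the
corresponding displacement is lost, biasing step length low by several
percent. Keeping integration on raw signals removes that bias while the
detection stage keeps its noise immunity. (The integration itself averages
noise; it does not need the filter.)

### Segmentation and events

Swing opens at an upward crossing of the filtered gyro norm above
20 deg/s and closes at the downward crossing; candidate phases shorter
than 0.1 s are merged shortest-first (an interior short phase fuses its two
like-phase neighbours). The heel strike for each swing is the minimum of
the signed sagittal angular velocity within
(onset, onset + stride_window_factor × mean stride], additionally capped at
the next swing onset. The sagittal axis is, in `auto` mode, the gyro axis
with the largest variance over swing samples; its sign is set so the
*median* over swing samples is positive — the median tracks the sustained
mid-swing dorsiflexion lobe and, unlike the mean, is immune to the narrow
deep strike pulse. Timing is coarse-to-fine: the filtered signal localises
the strike; the raw signal's minimum within ±60 ms, interpolated with a
three-point parabola, gives sub-sample timing. Ties break to the earliest
sample. A final swing whose search window overruns the trace is dropped
with a warning.

Note on phase ordering: the heel strike *precedes* the end of its swing's
threshold interval. Foot rotation persists briefly after ground contact
(the loading response), so the gyro norm falls below threshold some tens of
milliseconds after the strike. The detected foot-flat interval is therefore
a conservative subset of physical stance, which is exactly what the
zero-velocity update needs.

### Orientation

The complementary filter propagates the quaternion with the midpoint gyro
rate and, per sample, rotates the estimate toward the accelerometer-derived
vertical by (1 − α) of the tilt error (α = 0.98 at 128 Hz, i.e. a tilt time
constant of ≈ 0.4 s). Tilt blending is applied only under *sustained*
quasi-static conditions: every sample within ±0.15 s must have
‖accel‖ within 20% of g **and** gyro norm ≤ 20 deg/s. The window matters:
at movement transitions the accelerometer norm can pass through the
acceptance band while pointing well away from vertical (early push-off,
mid-swing lulls), and even a few such updates inject degree-level tilt
error, which leaks g·sin(error) into the horizontal acceleration. The
centred window is non-causal, consistent with this offline pipeline (the
zero-phase filter already is); a real-time variant would use a trailing
window and accept slightly larger transients.

### Integration and zero-velocity updates

Velocity is the trapezoidal integral of the world-frame, gravity-free
acceleration. Each foot-flat's mean raw velocity is its drift residual;
foot-flat samples are pinned to zero and the residual is removed across
the adjacent inter-flat stretch by a linear ramp (continuous with the
pinned stances). Position integrates the corrected velocity from the
quiet-standing origin, shared by both feet. Heel-strike positions are read
at the following mid-stance anchor (the flat's midpoint): the heel is
planted from strike through stance, so the positions coincide, and by
mid-stance the integrated track has settled through the strike transient.

### Step metrics

The two feet's strikes are merged in time order and must alternate;
violating strikes are dropped (warning) and steps bridging them discarded.
Each foot's anterior-posterior (AP) coordinate is its cumulative
along-track distance from the standing origin. This is the key
registration choice: each sensor's residual yaw-bias makes its track curve
slowly (a degree or two per minute), and any fixed projection axis
misassigns displacement on longer recordings, whereas stride displacement
*norms* are exactly invariant to per-foot heading drift and to any common
rotation of the traces (the tested yaw-invariance property). For the
straight-line walking this tool targets, along-track distance equals the
AP projection. The principal horizontal direction of all stride
displacements is still estimated (SVD) and reported as the walking axis.
Step k, ending with foot F's strike at t_k: step_time = t_k − t_{k−1},
step_length = AP_F(t_k) − AP_G(t_{k−1}) with G the opposite foot. The
first step after standing (roughly a half step) is retained, matching
per-step walkway output; `trim_steps` can drop k steps from each end.

### Pairing against a reference

Measured and reference series are paired by strike order after removing
the best common clock offset (median strike-time difference over the
best-scoring alignment lag), with a 0.25 s tolerance; unmatched
leading/trailing steps are dropped, and more than 20% unpaired steps in
the overlap raises an error carrying a diagnostic table. Per-step percent
error is 100·|measured − reference|/reference.

## Agreement statistics

*Passing–Bablok*: all pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i),
i < j, excluding undefined (Δx = 0, skipped with a warning if > 10%) and
S_ij = −1; offset K = #{S_ij < −1}; slope = shifted median (rank shifted
by K); 95% CI from ranks M1 = round((N − w)/2), M2 = N − M1 + 1 with
w = 1.96 √(n(n−1)(2n+5)/18); intercept = median(y − b·x), its CI evaluated
at the opposite slope bounds. The implementation is vectorised; the test
suite checks it slope-for-slope against a loop-based exhaustive oracle.

*ICC(2,1)* (single measure, absolute agreement, two-way model, k = 2
raters): ICC = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the
two-way ANOVA mean squares, with the McGraw–Wong F-based 95% CI
(Satterthwaite denominator df). Cross-checked against pingouin's ICC(A,1)
and a directly assembled ANOVA oracle.

*Bland–Altman*: differences d = reference − test (so a test reading high
gives a negative bias), bias = mean(d), LoA = bias ± 1.96·SD(d) (sample
SD); percent mode expresses each d relative to the pair mean. Plot data
(pair mean, difference) are exported rather than plotted.

A caveat inherited from standard practice: steps are pooled across passes
(and, in real studies, subjects) despite within-subject correlation; the
pooled ICC is reproduced as-is and should be read accordingly.

## Synthetic gait model

The simulator emulates the standard validation protocol: quiet standing
(3 s), then straight-line walking. Step times and lengths are lognormal
with configurable mean and coefficient of variation; a left-right
step-length asymmetry a splits the means as (1 ± a/200); the first step is
a half step (gait initiation). Presets encode population statistics of
short-to-moderate validation cohorts: `pd_preset` (step length
0.59 m ± 0.11, step time 0.73 s ± 0.26, blunted 24° pitch excursion) and
`ya_preset` (0.68 m ± 0.09, 0.59 s ± 0.06, 32°).

Per swing of duration D ending at strike time T:

- AP translation is minimum-jerk; vertical heel lift is h·sin²(πs)
  (h = 3 cm), so the vertical minimum falls exactly at T — the ground-truth
  strike convention.
- Sagittal angular velocity is a raised-cosine dorsiflexion lobe starting
  0.25·D *before* translation (the heel-off/push-off foot roll of terminal
  double support — this is why a rate threshold fires before displacement
  begins) plus a sharper negative raised-cosine pulse centred at T (the
  strike signature), areas matched so net pitch per stride is zero. The
  pulse is symmetric about T so the detection convention (sagittal-gyro
  minimum) coincides with the truth convention (vertical minimum) by
  construction: recovery error measures algorithm error, not a definition
  mismatch.
- Swing duration is swing_fraction × stride, clipped to [0.25, 0.8] s:
  step-to-step timing variability loads on stance duration (hesitation),
  as in real — especially parkinsonian — gait. The strike pulse half-width
  is 0.18·D floored at 0.12 s (impact/loading duration does not scale with
  cadence).
- Ideal sensor signals are the world acceleration plus gravity rotated
  into the foot frame through the true orientation, and the true body
  rates; Gaussian noise and a constant gyro bias are added last. The same
  seed reproduces traces bit-for-bit.

What the simulator does **not** emulate: toe-off plantarflexion spikes
(omitted so the truth tables have a single negative extremum per stride),
lateral sway and step width, turning, treadmill gait, festination or
freezing episodes, soft-tissue/mounting artefacts, magnetometer channels,
and sensor-clock jitter. Passing the validation battery therefore shows
the pipeline recovers steps whose event signatures match the modelled
morphology under Gaussian sensor errors — not that it is robust to every
failure mode of real recordings.

## Validation experiment design

Lab validation of such systems happens in short instrumented-walkway
passes pooled across repetitions. The bundled experiment mirrors that:
10 passes × 20 steps per replicate (200 steps), with accelerometer noise
0.05 m/s², gyro noise 0.5 deg/s and gyro bias 0.3 deg/s per axis;
`scripts/acceptance.py` pools five replicates for the statistics.
Pooling short passes rather than simulating one 200-step walk is
deliberate: step length compares the two feet's integrated tracks, and
with independent sensors the inter-foot registration drifts slowly
(difference of cumulative arcs), so per-step accuracy over a
walkway-length pass is the quantity these systems are validated on.
A continuous multi-minute walk is outside the validated envelope — a known
limitation, shared by the two-independent-IMU measurement principle
itself rather than this implementation.

## Numerical choices

- Edge handling for the zero-phase filter: reflect ("even") padding of one
  settling length (3 × filter order); results are bit-reproducible.
- Trapezoidal rule for both integrations; quaternion propagation uses the
  midpoint rate with axis-angle increments and per-sample renormalisation;
  sign continuity is enforced (q·q_prev ≥ 0).
- Heel-strike ties break to the earliest sample; the parabolic refinement
  is skipped when the vertex offset exceeds one sample or curvature is
  non-positive.
- Pinned-flat + ramp drift removal is exact for drift that is constant
  within a step; the linear ramp choice (over a constant offset) keeps the
  corrected velocity continuous at phase boundaries.
- CSV output uses 10 significant digits (round-trips to 1e-9 relative).

## Known limitations

- Step length is AP progression; the vertical strike coordinate is
  computed but unused (no stair/slope support).
- The population-average stride duration used to bound the strike search
  is estimated per trace (mean swing-onset interval), not taken from a
  population table.
- ICC/PB/BA on pooled steps ignore within-subject correlation (see above).
- The real-time (causal) filter mode exists but the validated defaults are
  the offline, non-causal ones.
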