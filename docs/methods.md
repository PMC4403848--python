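# Methods

## Pipeline

A TUG trial is a 60 Hz multi-channel recording: per sensor site, tri-axial
acceleration and angular velocity plus a unit orientation quaternion
stream from the suit's fusion algorithm. The pipeline is offline and
whole-trial; nothing is causal or streaming.

**Conditioning.** Each analyzed channel passes through detrend →
normalize → ideal band-pass, in that order. Detrending removes the
least-squares *linear* trend: drift is modeled as slow and near-linear,
and a mean-only removal would leave ramps that defeat the peak logic.
Normalization divides by the absolute maximum, making amplitudes unitless
and subject-comparable; an all-zero (or numerically zero, < 1e-12)
signal is rejected as degenerate. The band-pass is a brick wall applied
in the DFT domain of the full unpadded trace: bins with |f| in [w1, w2]
are kept with unit gain (inclusive edges), all others zeroed, and the
real part of the inverse transform returned. No windowing or tapering is
applied — the ideal filter is a projection by definition and its edge
ringing is accepted and tested for (idempotence, linearity, energy
non-increase). The low cut w1 = 0.0025 Hz removes only the DC bin on any
realistic trial length; the high cuts are per-channel, per-transition
parameters (below). The order normalize-then-filter (rather than the
reverse) is a documented choice; the conditioned-trace invariants
(max |x| ≤ 1, zero mean) are defined under it.

**Detection.** Activity peaks are strict local extrema (plateaus owned by
their first sample, for determinism) whose |value| exceeds 30% of the
trace maximum, thinned so no two survive within 1.0 s (the larger wins;
the earlier breaks ties). Standing and sitting are trunk a_z peaks
classified by the sign of the hip a_y derivative at the peak (a ±2-sample
neighborhood mean breaks exact zeros; a still-ambiguous event raises).
Turning requires a same-sign head ω_y peak within ±0.5 s of each trunk
ω_y peak — head and trunk yaw are near-synchronous in a whole-body turn —
and the head peak's sign gives the direction (positive yaw = left).
Walking is a 500 ms sliding window over hip ω_x conditioned to the
Nyquist frequency (30 Hz): a window is positive when it contains ≥ 2 zero
crossings *and* its RMS exceeds 0.1× the whole-trial RMS. The
zero-crossing count admits stride frequencies from about 1 Hz up; the RMS
gate rejects quiescent sensor noise, which crosses zero constantly at
negligible amplitude. The per-sample label fusion gives Turning
precedence over Walking (turning involves steps, so the walking detector
fires during turns by design) and lets the stand/sit square regions
override Walking.

Detection uses wider bands than segmentation: trunk/head ω_y are
conditioned at 2.0 Hz for peak-finding, above the sub-hertz cuts
calibrated for boundary precision. The narrow cuts smear the pulse and
ring at its edges — good for localizing boundary minima, bad for finding
a stable, verifiable peak. The stand/sit detection channels reuse the
1.57 Hz sit-to-stand cut.

**Segmentation.** Each of the seven transitions is anchored to one
detected activity peak and one side: sit_to_stand / stand_to_walk_out are
the left/right bounds of the stand-up peak; walk_out_to_turn /
turn_to_walk_in bracket the first turn; walk_in_to_turn / turn_to_stand
bracket the second; stand_to_sit is the right bound of the sit-down peak.
On each configured channel the peak is re-located on that channel's own
band (the largest-|value| local extremum within ±1.5 s of the anchor),
and the bound is the first local extremum of opposite polarity scanning
outward sample by sample — first minima around a maximum-type peak,
generalizing the turn example where minima flank the yaw peaks. Reaching
the trace boundary returns the boundary time; boundary-fallback
candidates are dropped from the combined mean when interior candidates
exist (boundary times are cropping artifacts), with a log message. The
combined transition time is the mean of the per-channel candidates.
Strict monotonicity of the seven combined times is enforced; violations
raise with the offending pair named.

Default sensor combinations follow the flow-chart assignments:
sit_to_stand = trunk a_z (1.57 Hz) + left-knee angle (8.30 Hz);
stand_to_walk_out = trunk a_z (2.44); walk_out_to_turn = trunk ω_y (1.32)
+ hip ω_y (0.98); turn_to_walk_in = hip ω_y alone (0.53);
walk_in_to_turn = trunk ω_y (1.00) + hip ω_y (0.59); turn_to_stand =
trunk ω_y (1.00) + hip ω_y (0.81); stand_to_sit = trunk a_z (1.07). The
frequency table's "v_y" entries are read as angular velocity ω_y, and its
two cells that name other sites for sit-to-stand (hip ω_x 0.69) and
stand-to-sit (hip a_z 1.07) remain encoded in `TABLE1_FREQUENCIES` and
selectable through config; the default for stand-to-sit keeps the trunk
channel (per the flow chart) at the published 1.07 Hz cut. All of this is
overridable via YAML (`load_config`).

**Joint angles.** Quaternions are scalar-first [w x y z] with the
Hamilton product. The joint angle between adjacent segments is
θ = 2·acos(clamp(|w(q_Δ)|, 0, 1)) in degrees, where
q_rel = q_prox⁻¹ · q_dist and q_Δ = q_ref⁻¹ · q_rel against the standard
pose captured at t = 0. Taking |w| resolves the q/−q double cover and
enforces θ < 180° in one step. Streams are sign-continuity corrected
(flip when the dot product with the previous sample is negative) before
angle extraction. Knee = thigh vs. shin; hip = pelvis vs. thigh. No
Euler decomposition is attempted — the method uses a single scalar angle.

**Calibration.** The high cut for a (channel, transition) pair minimizes
Σ_k (T_ref,k − T_sensor,k)² over an exhaustive grid of 2000 evenly spaced
frequencies in [0.5, 10] Hz, endpoints included; ties resolve to the
lowest frequency, and the full cost curve is retained. Failed estimations
are excluded with a warning by default (a fixed penalty is configurable).
References here are simulator ground truth; the human-examiner times the
original procedure used are not available, and the examiner process is
explicitly replaced. Grid evaluation caches the per-trial detrended,
normalized spectrum so each grid point costs one masked inverse FFT.
`select_sensor_combination` scores every subset of candidate channels by
the cost of their mean estimate, each member at its own calibrated cut.

One property of the synthetic cohorts worth knowing: cost curves are
piecewise constant in w2 (estimates move in whole samples) and several
channels have a broad, flat-bottomed basin in which within-basin cost
differences are ~1e-3 s². The *argmin* can hop between near-ties there
even though the attained cost is stable; the convergence check in the
acceptance suite therefore uses a channel/transition with genuine
curvature (hip ω_y at walk-in-to-turn), where the optimum is stable to
one grid step from 12 subjects on.

**Scoring.** Sensitivity and specificity are computed over ground-truth
segment instances (6 per trial). A Standing/Turning/Sitting segment is a
true positive when an event of its activity has its peak inside it; a
Walking segment when at least half its samples are labeled Walking. The
negative universe is not operationally defined in the source procedure;
here it is one opportunity per (trial × segment slot): a spurious event
of an activity — outside every true segment of that activity, or a
duplicate — consumes one of that activity's slots as a false positive,
and untouched slots count as true negatives, so TN + FP equals the number
of segment instances. ΔT is the cohort mean absolute difference between
estimated and reference transition times per transition, with the sample
standard deviation of the signed differences as the spread.

## The synthetic generator

`simulate_tug` builds a trial from phase-boundary times
(lead-in 0.75 s → stand 1.5 s → walk d/v → turn 2.0 s → walk → turn →
sit 1.5 s → lead-out 0.75 s) and emits exactly those boundaries as the
seven ground-truth transitions. Defaults: walking speed 1.0 m/s and
stride frequency 1.8 Hz (typical self-paced values for healthy older
adults), giving 28.5 s at 10 m and 18.5 s at 5 m; the published task
showed a larger 10 m/5 m duration ratio because real subjects do not hold
identical speeds across distances. Channel templates:

- trunk a_z: raised-cosine domes spanning the stand-up and sit-down
  phases — single dominant postural peaks;
- hip a_y: smooth steps (up at stand-up, down at sit-down) so its
  derivative signs the two trunk peaks;
- trunk/head ω_y: one half-sine lobe per turn, head at 0.8 amplitude;
  the two turns go opposite ways by default (out-turn left, pre-sit turn
  right), as when the subject turns toward the chair to sit. The strict
  concavity of the half-sine keeps the *filtered* pulse unimodal, so the
  outward extremum scan meets no interior minima;
- hip ω_y: the same turns with a fast-rise/slow-fall skew (the pelvis
  yaws hardest stepping into a turn and derotates gradually stepping
  out), plus a 0.25-amplitude stride leak;
- hip ω_x: the stride oscillation under a smooth on/off envelope during
  both walking bouts;
- thigh/shin quaternions: a transient 90° knee-flexion excursion spanning
  each postural phase, about the sensor x axis, with small random-axis
  angular noise;
- every inertial channel: linear drift (0.01 units/s) plus white Gaussian
  noise (sd 0.03 of unit pulse amplitude — a few percent, consistent with
  band-limited IMU noise after amplitude normalization).

Every activity pulse carries small opposite-sign lobes centered exactly
at its phase boundaries — the anticipatory and braking counter-motions
visible in real recordings, and precisely the feature the first-extremum
rule keys on. Their depths stay well under the 30% peak threshold
(0.12–0.15 of the main lobe; deeper and wider, 0.40/1.5 s, on the hip yaw
channel, whose counter-swing is a genuine stride) so they never register
as activity peaks. This is the generator's central modeling commitment:
it emulates data for which the published segmentation rule is *valid*.
What passing tests therefore show is that the implementation executes the
method correctly and recovers truth when the method's premise holds; they
do not show that the premise holds for any particular real sensor suit,
mounting, or population. Other unmodeled features of real data: soft-
tissue artifact, magnetometer-fusion drift in the quaternions,
non-stationary gait, pauses, and upper-limb channels.

`simulate_cohort` draws per-subject factors N(1, variability) (default
0.05, clipped at ±2.5 sd) on speed, stride frequency and phase durations,
then gives each trial a fresh noise seed; everything is deterministic
under a fixed seed.

## Numerical choices and degenerate inputs

- Time is seconds from trial start; samples 0-based at 60 Hz. Reported
  millisecond quantities are converted at the presentation layer.
- Local extrema are strict; plateaus take their earliest sample. Peak
  thinning is greedy, strongest first, earlier-time tiebreak.
- The square indicator is the contiguous region around the peak where the
  peak-oriented trace exceeds 30% of the peak amplitude; if the peak
  sample itself is below threshold the region degenerates to that sample.
- Transition estimates discard boundary-fallback candidates when interior
  ones exist; if all candidates are boundary times, their mean is used.
- acos inputs are clamped to [0, 1]; zero-norm quaternions raise.
- Trials must have uniform rate and length across channels; orientation
  streams are renormalized on construction and rejected beyond 1e-3 from
  unit norm.

## Scale of the shipped experiments

Tests and the acceptance script run cohorts of 16 subjects × 2 trials per
distance (the study design), which complete in seconds; the full
2000-point calibration with its 12→16-subject convergence sweep runs in
under a minute. These sizes are the package's standard experiment
configuration.

## Known limitations

- Transition-time accuracy at the lowest calibrated cut (0.53 Hz) is
  resolution-limited: the mean error on turn-to-walk-in is ~0.25 s at
  default noise, and strong between-subject duration jitter can push
  single trials somewhat past 0.3 s. This is a property of brick-wall
  filtering at w2 × pulse-duration ≈ 1, not of the implementation.
- The examiner-variance analysis of the original procedure is not
  reproduced (no human annotations); calibration references are simulator
  truth.
- The proprietary suit file format is not parsed; trials are exchanged in
  the documented columnar CSV. No magnetometer channel is synthesized or
  used.
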