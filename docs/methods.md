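# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The planar link-segment model

The body is a sagittal-plane chain: a foot, shank, and thigh per leg
(the two legs move identically and mirror mediolaterally, matching a
bilateral landing) and a pelvis that carries the lumped head-arms-trunk
(HAT) remainder. Coordinates: x anterior, y vertical up, z mediolateral.
Segment lengths are fixed fractions of standing height; inertial
parameters (mass fraction, CoM position, radius of gyration) come from
bundled plain-text tables — the adjusted-Zatsiorsky adult-male fractions
by default, the classical cadaver fractions as an alternative. The mass
fractions of each table sum to one (to 1e-3) including the HAT remainder.

Joint-angle conventions (all zero in neutral standing):

- knee and hip flexion positive, 0 deg = full extension;
- ankle dorsiflexion positive, with the neutral offset calibrated from the
  subject's static trial;
- pelvic anterior tilt positive when the anterior pelvis markers dip below
  the posterior ones. Hip flexion is the angle between the thigh line and
  the pelvis line, which makes all four angles invariant under rigid
  rotation of the marker cloud. (A literal "line above the horizontal"
  tilt convention was considered and rejected: combined with the reference
  joint-angle values it implies a near-horizontal thigh at touchdown and a
  CoM descent too small to absorb the drop momentum at physiological
  ground-reaction forces.)

Angles are computed from marker-defined segment lines (hip-knee,
knee-ankle, ankle-toe, PSIS-ASIS), not functional joint centres:
functional calibration needs 3-D star-arc motions that are outside the
scope of a planar, desk-scale model. This is the main deliberate
divergence from optical-capture practice and is shared by generator and
analysis, so it cancels in recovery checks but would not cancel against
real laboratory data.

## The synthetic trial generator

A trial runs through six phases: standing hold on the platform, ballistic
drop, landing (touchdown to peak knee flexion), propulsion (to take-off),
flight-phase relaxation, and a frozen flight hold. The generator's
central design constraint is *dynamic self-consistency*: markers and
forces must be the same physical motion. The GRF is therefore derived
from the whole-body CoM, F = m (g + a_com), with the CoM computed from
segment kinematics and the anthropometric masses — never faked
independently.

Each contact phase is a **time-warped pose path**:

1. The joint angles travel along a quadratically bent segment in angle
   space between the phase's end postures. With the bend bounded by 80%
   of each joint's excursion, every joint moves monotonically, so the
   prescribed touchdown and peak angles are exact and overshoot is
   structurally impossible. The bend direction/magnitude is chosen by a
   small search that balances the CoM leverage |d com_y / d xi| between
   the phase ends (a weak end would concentrate joint velocity there).
2. A degree-7 CoM-height profile prescribes the timing: it leaves the
   touchdown height at the ballistic entry speed sqrt(2 g h_drop), stops
   (with zero velocity, acceleration, and jerk) at the peak-flexion
   height, and rises to take-off at the speed that realizes the
   prescribed jump height. Its boundary conditions make the implied GRF
   zero at touchdown and take-off, rising with a configurable CoM jerk
   (`impact_jerk`, default 500 m/s^3 — the generator's free
   impact-sharpness parameter), so event detection at the 10 N threshold
   locates the contact to within about one force sample.
3. The warp xi(t) inverts the (strictly monotone) CoM height along the
   pose path via a cubic spline; the inversion is well conditioned because
   the path's CoM slope never vanishes (plans violating monotonicity or a
   0.05 m leverage floor are rejected as infeasible).

Take-off speed is solved by fixed-point iteration because the
pelvis-to-CoM offset changes while the pose relaxes in flight; jump height
is defined against the pelvis-marker centroid, as in the analysis. A
propulsion phase slower than the polynomial profile family supports is
split into a slow early rise near the deep posture (GRF near body weight)
plus a standard-tempo push, joined with C^3 continuity.

Flight phases are strictly ballistic (CoM parabola; GRF identically
zero); the drop and relaxation splines match position, velocity, and
acceleration at the events, so marker trajectories are C^2 across
touchdown and take-off and the contact-phase vertical impulse equals
m (v_takeoff − v_touchdown) by construction (validated to < 1%, limited
only by finite-difference discretization).

Measurement noise is i.i.d. Gaussian per frame per channel: marker SD
0.5 mm, force SD 2 N — typical optical-capture and plate noise, small
relative to the 15 Hz filter. All randomness flows from a single seed;
identical seeds give bitwise-identical trials.

### Condition presets and cohort sampling

The presets `baseline` and `damaged48h` carry the pre-exercise and 48-h
post-eccentric-exercise group means of the reference athlete cohort
(touchdown and peak angles, phase durations, jump height); the matching
between-subject SDs are stored alongside. Whole studies are sampled as:

- subjects from the reference population (mass 78.9 ± 8.5 kg, height
  1.811 ± 0.063 m);
- per joint, one standard-normal deviate per session shared by the
  touchdown and peak angle (so peaks stay above touchdown values), with
  between-session correlation `SESSION_RHO = 0.85` — typical of repeated
  drop-jump testing, and placing the implied paired effect sizes of the
  prescribed outcomes inside the a-priori range (1.05-1.46) assumed by
  the reference study design;
- phase durations from the reference statistics, clamped to the
  dynamically feasible tempo band kappa = v T / |delta CoM| of the
  sampled postures (about 1.45-2.15). The rigid HAT segment
  underestimates CoM excursion (no trunk flexion), so the fastest deep
  landings are infeasible for the model: the clamp truncates the lower
  duration tail and shrinks duration SDs by roughly a third relative to
  the reference values, while means and pre/post effects are preserved.
  Long propulsions are always feasible via the piecewise profile;
- the take-off configuration (knee 30, hip 18, ankle -15 deg) was
  calibrated once so that this feasible band brackets the reference
  duration distributions;
- a few percent of unconstrained draws combine postures with no feasible
  contact trajectory at all; they are rejection-resampled, as real
  (necessarily feasible) coordination would be.

What passing the study-level tests does and does not show: the generator
reproduces the prescribed kinematics, phase structure, and jump height,
and the paired design's power for those outcomes; the *kinetic* outcome
magnitudes (GRF peaks, moments, powers, stiffness) are emergent from the
planar model and are larger than laboratory values (peak landing GRF
4-5 BW rather than ~2 BW) because the rigid HAT shortens the CoM braking
distance. Their signs and directions of change match the reference
pattern and are asserted; their magnitudes are not.

## Analysis pipeline choices

- Events are detected on the **raw** summed vertical GRF (threshold 10 N,
  first sample strictly above / first subsequent sample at or below),
  with a 20 ms debounce that merges sub-debounce gaps and discards
  sub-debounce spikes; the analyzed landing is the first contact of at
  least 100 ms. Filtering happens after event detection.
- "Fourth-order zero-lag Butterworth at 15 Hz" is implemented as a
  2nd-order filter applied forward and backward (the dominant biomechanics
  convention; single-pass mode is available), with odd-reflective edge
  padding and no cutoff-correction factor.
- Forces are low-passed at the shared 15 Hz cutoff and then decimated to
  the kinematic rate (filter-then-pick; aliasing is impossible after the
  low-pass). Whether to downsample force or upsample kinematics is not
  dictated by the reference protocol; downsampling was chosen.
- Accelerations come from double-differentiated filtered marker
  positions (central differences, one-sided at the edges).
- Inverse dynamics is a bottom-up planar Newton-Euler recursion with the
  GRF applied at the centre of pressure; the free moment is ignored (a
  planar model has no vertical-axis torque). Only the dominant leg is
  analyzed by default. A COP falling > 10 cm outside the foot's marker
  bounding box in loaded frames raises a warning.
- Knee stiffness uses the moment and angle values sampled **at** the
  touchdown and peak-flexion instants (literal ratio of changes), not
  phase extrema; an `extrema` mode is available.
- Phase durations are reported at force-rate (1 ms) resolution for the
  contact boundaries and kinematic-rate (5 ms) resolution for the peak
  knee flexion instant; landing + propulsion = total contact exactly.
- Peak searches use the phase windows (landing = touchdown..peak knee
  flexion inclusive; propulsion = the remainder of contact, exclusive);
  ties break to the earliest frame.
- Pelvic tilt is measured against the laboratory horizontal, not a
  subject-specific static reference (the latter would zero the reported
  touchdown tilt).

Recovery accuracy through the full pipeline (noise-free presets): the
15 Hz zero-lag filter biases the angle waveforms by up to about 0.2 deg
at touchdown and 0.1 deg at the landing peaks; durations are recovered to
about 1 ms (contact, force-defined) and 5 ms (landing/propulsion,
kinematic-frame quantized); jump height to < 0.1 cm.

## Statistics layer

- ICC is fixed to ICC(3,1) — two-way mixed effects, consistency, single
  measurement — computed from the subjects x visits mean squares;
  SEm = pooled SD * sqrt(1 − ICC); CV% is the mean over subjects of
  (SD of the two visits / their mean) * 100 with 0/0 taken as 0.
  Identical test-retest data with zero subject variance (a soreness scale
  at floor) report ICC 1.0, CV 0, SEm 0 and are flagged degenerate rather
  than returned as NaN.
- The one-way repeated-measures ANOVA is the classical
  F = MS_time / MS_error with sphericity assumed; with two timepoints it
  equals the squared paired t statistic identically.
- All tests are two-tailed at alpha = 0.05; no multiple-testing
  correction is applied, mirroring the emulated analysis plan.
- A-priori power for a paired design uses the noncentral t distribution
  with noncentrality d_z sqrt(n). At d_z = 1.05 and two-tailed
  alpha = 0.05 the smallest n reaching 80% power by this calculation is
  smaller than the n = 12 quoted in the reference design (whose power
  software configuration is not recorded); the package reports its own
  calculation.
- The muscle-damage panel generator draws each indicator from the
  configured per-timepoint mean/SD with a shared subject random effect
  (within-subject correlation 0.5 by default), clips soreness to the 0-10
  scale and CK at zero. The torque reliability emulation uses a 300 Nm
  between-subject mean (SD 45 Nm) with a within-subject test-retest CV of
  4.27%.

## Numerical details

- Sample indices are 0-based, t = index / rate, intervals half-open.
- TRC files are written in millimetres and converted on read; marker
  dropouts up to 10 frames are filled with a cubic spline through the
  valid frames, longer or boundary gaps are errors.
- The warp inversion spline samples the pose path at 801 points; CoM
  Jacobians use central differences with a 0.01 deg step.
- Trials are planned at 200 Hz (markers) and 1000 Hz (forces); the trial
  spans a 0.1 s platform hold, the 0.247 s drop, the prescribed contact,
  and 0.4 s of flight.
- Study runs derive every per-trial seed deterministically from the
  config seed; reports embed the config SHA-256 digest.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to keep the whole suite
desk-scale while leaving Monte-Carlo error well below the asserted
tolerances: 10,000 null replicates for the paired-t type-I rate
(tolerance ±0.01), 2,000 panels for ICC recovery (tolerance
max(3 SE, 0.005), the 0.005 covering the estimator's small-sample bias),
200,000 replicates for the power cross-check (tolerance 0.005), and 100
seeded 13-subject studies for the study-level power criterion.

## Known limitations

- Sagittal plane only; no frontal/transverse mechanics, no knee
  ab/adduction or tibial rotation.
- Rigid HAT segment: no trunk flexion, hence compressed CoM excursions,
  elevated kinetic magnitudes, and a narrowed feasible band of phase
  tempos (see above).
- Markers sit at joint centres; no soft-tissue artefact, marker offset,
  or calibration error models.
- The GRF is split equally between the plates (bilateral symmetric
  contact); asymmetry is not modelled.
- The central-difference derivative is exact only to O(dt^2): at 200 Hz
  its truncation error on the fastest landing transients reaches
  ~1 deg/s in angular velocity, and a 5 Hz component passes the 15 Hz
  dual-pass filter attenuated by 1.2% — both bounds are asserted, not
  hidden, in the test suite.
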