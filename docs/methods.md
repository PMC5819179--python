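# Methods

## Arm model

The upper limb is reduced to a 7-revolute-joint serial chain: a spherical
shoulder (q1 abduction-adduction, q2 flexion-extension, q3
internal-external rotation), an elbow hinge (q4 flexion-extension) and a
spherical wrist (q5 pronation-supination, q6 ulnar-radial deviation, q7
wrist flexion-extension), joined by the upper arm (`l_u`) and forearm
(`l_f`). The chain uses the classical (distal) Denavit-Hartenberg
convention, link transform `Rz(θ)·Tz(d)·Tx(a)·Rx(α)`, with

| i | θ        | d    | a | α     |
|---|----------|------|---|-------|
| 1 | π/2 + q1 | 0    | 0 | π/2   |
| 2 | 3π/2 + q2| 0    | 0 | π/2   |
| 3 | q3       | l_u  | 0 | −π/2  |
| 4 | π/2 + q4 | 0    | 0 | π/2   |
| 5 | π/2 + q5 | l_f  | 0 | π/2   |
| 6 | π/2 + q6 | 0    | 0 | π/2   |
| 7 | π/2 + q7 | 0    | 0 | π/2   |

The elbow point is the origin of frame 3 (end of `l_u`), the wrist point
the origin of frame 5 (end of `l_f`; frames 5–7 share it). Under this
convention the shoulder-wrist distance satisfies
`‖W−S‖² = l_u² + l_f² − 2 l_u l_f sin(q4)`, so the flexion angle follows
from the law of cosines as `q4 = arcsin((l_u²+l_f²−‖W−S‖²)/(2 l_u l_f))`,
with q4 = −π/2 the fully extended arm; the forward-kinematics test suite
asserts this roundtrip, which fixes the sign convention unambiguously.

Anatomical joint ranges are treated as the soft band [−π/2, π/2]: the
tracker only warns when a joint leaves it (patients exceed nominal ranges),
while the closed-form initializer enforces it strictly to select among
branches.

## Closed-loop inverse kinematics with the augmented Jacobian

The 6×7 geometric Jacobian of the hand pose is built column-wise from the
chain axes, `[z_{i−1} × (p_w − p_{i−1}); z_{i−1}]`. The swivel angle α is
the signed angle, about the shoulder→wrist axis, between the arm plane
(S, E, W) and the reference plane through S, W and a fixed reference
vector; the reference vector defaults to the gravity direction implied by
the sensor mounting and is configurable — any fixed choice is admissible
because targets and Jacobian share it. The 1×7 swivel Jacobian is computed
by central finite differences of α through the forward kinematics (step
1e-6 rad); no analytic form is attempted, and the finite-difference
truncation error (≲1e-9 for this smooth map) is far below the tracking
tolerances. Its last three entries are identically zero since α depends
only on S, E, W, which q5–q7 do not move.

Joint velocities come from the damped least-squares inverse
`J*_A = J_Aᵀ(J_A J_Aᵀ + k² I)⁻¹` of the stacked 7×7 system, driven by the
recorded-stream feedforward plus proportional feedback, and are integrated
with the explicit Euler step at the sampling interval.

Parameter defaults, with units and rationale:

- **K = diag(1.5, …, 1.5) (1/s)** on all seven error rows. The error
  vector mixes metres (rows 1–3) and radians (rows 4–7); the uniform gain
  accepts that heterogeneity. It sets the closed-loop error time constant
  to ≈0.67 s, slow enough to filter sensor noise, fast enough to cancel
  integration drift.
- **k² = 1e-4 (damping)**. In metre/radian task coordinates the augmented
  Jacobian's singular values over the work range are ≈0.13–2.0; k²=1e-4
  attenuates them by <1% while bounding the velocity gain near
  singularities by 1/(2√k²) = 50. Damping factors quoted for other
  (e.g. millimetre-scaled) unit conventions do not transfer to SI
  coordinates: a damping of 0.5 in this unit system would attenuate the
  smallest arm singular values ~30-fold and make the tracker lag by
  several degrees even on noiseless data.
- **Δt = 0.01 s**, the 100 Hz magneto-inertial sampling rate.

The desired twist is backward-finite-differenced from consecutive
end-effector poses (orientation rate via the axis-angle of the relative
rotation), and the swivel rate from consecutive swivel targets with
wrapping to (−π, π]; robot logs provide poses, not velocities. The
7-row pose error uses the axis-angle vector of `R_d R_cᵀ` for orientation —
one admissible realization of the error vector, exact to third order for
small errors — and wraps the swivel row. Per-step diagnostics record the
pose-error norm and cond(J_A); condition numbers above 1e6 raise a warning,
never an abort.

## Elbow estimation from one accelerometer

Quasi-static model: the accelerometer, strapped to the upper arm with its
Y axis pointing from shoulder to elbow, reads the gravity direction in its
own frame, normalized by g. At the reference posture (all joints zero, arm
hanging) the reading is (0, 1, 0). Samples whose magnitude departs from
1 g by more than 0.2 g are rejected (dynamic acceleration) and the
previous elbow estimate held.

Given a sample v, the minimal rotation aligning it with the reference
reading is built by the Rodrigues form `I + M + M²(1−cosθ)/sin²θ` on the
axis `V = (0,1,0) × v`; the matrix is oriented so that it maps **v onto
the reference reading** (the testable alignment contract), with explicit
branches for the near-zero (identity) and antiparallel (180° about X)
singularities below sinθ = 1e-8. Any sensor orientation compatible with
the sample is this matrix pre-multiplied by a rotation γ about the gravity
direction in the reference sensor frame. Requiring the candidate Z axis,
mapped to the robot frame through the reference mounting rotation, to be
orthogonal to W − S yields `a·cosγ + b·sinγ + c = 0` with two roots (an
explicit error when |c| > √(a²+b²): sensor inconsistent with the
shoulder-wrist geometry). Each root gives an accelerometer pose anchored
at the shoulder and an elbow candidate `l_u` along its Y axis.

**Candidate selection.** The anatomical rule — the sensor Z axis points
along the arm-plane normal cross(W−E, S−E) — is exact but not always
decisive: each candidate's S, E, W triangle lies in that candidate's own
sensor plane, so each dot product is exactly ±1, and once the mirrored
candidate's elbow crosses the shoulder-wrist line both dots are +1 (about
half of random interior postures; always decisive, and always correct,
outside that region). Ties are broken by forearm-length consistency —
only the true candidate also satisfies ‖W−E‖ = l_f (correct on 2000/2000
random interior postures, with a documented 1 mm indifference margin) —
then by temporal continuity with the previous elbow point, then by the
larger dot. A fully extended arm makes every candidate normal vanish;
selection raises, and the tracker holds the previous branch.

The elbow pose composes the selected sensor orientation with the fixed
elbow-in-sensor mounting rotation; on noiseless synthetic data it matches
the forward-kinematics elbow to 1e-9 m and machine-precision rotation.

## Closed-form initial pose

With the shoulder pose (measured at the start), the wrist pose (robot) and
the elbow pose (accelerometer) known at the first sample, the shoulder
block `base⁻¹·T_elbow` and wrist block `(base⁻¹·T_elbow·A4)⁻¹·base⁻¹·T_wrist`
are extracted in closed form. Reading n, o, a as the rows of each rotation
block:

- shoulder branch (i): q1 = atan2(−n_y, o_y),
  q2 = atan2(a_y, √(n_y²+o_y²)), q3 = atan2(a_z, −a_x); branch (ii) is the
  second atan2 root — negated square root, both q3 signs flipped, **and q1
  shifted by π** (the shift is required for the branch to reproduce the
  rotation through the forward kinematics, which the test suite asserts
  for both branches);
- wrist branch (iii): q5 = −atan2(n_y, o_y), q6 = arcsin(a_y),
  q7 = −atan2(a_x, a_z); branch (iv) is the π-complement of each.

q4 comes from the law of cosines above (arcsin argument clamped within
1e-9 to absorb measurement round-off; beyond that the limb lengths are
inconsistent with the data and an error is raised). Of the four
shoulder×wrist combinations exactly one lies in [−π/2, π/2]⁷ for interior
postures (verified over 10³ random draws per run); boundary ties are
broken by the smallest Σ|q_i|. At the gimbal conditions |q2| = π/2 or
|q6| = π/2 the atan2 pairs are underdetermined; the free angle is set to 0
and the solution flagged degenerate.

## Synthetic data generator

`generate_joint_trajectory` produces per-joint sums of three random
low-frequency sinusoids (0.03–0.12 Hz) about a mid-range rest posture
(0.30, −0.35, 0.25, 0.45, 0.20, −0.15, 0.10 rad), emulating slow
point-to-point reaching. Amplitudes are scaled so every joint stays inside
(−π/2+0.1, π/2−0.1) and below 0.5 rad/s — the quasi-static regime in which
the accelerometer model is valid. Everything is deterministic given the
seed.

`simulate_recording` renders the three sensor streams by forward
kinematics: the end-effector pose is the wrist frame; the accelerometer
sample is the mounting-implied gravity direction rotated into the current
sensor frame (so the reference posture reproduces the (0,1,0) reference
reading by construction, for any mounting); optional Gaussian noise is
added per stream. Shoulder drift emulates trunk compensation: the *true*
shoulder oscillates (moving the rendered poses and implicitly the joint
ground truth's relation to them) while the *recorded* shoulder series
keeps the initially measured position — the algorithm's fixed-shoulder
assumption is violated exactly as in a real session.
`inject_shoulder_steps` instead shifts the recorded series discontinuously
(≤0.1 m) to probe tracker stability under per-step shoulder input.

Default fixture geometry: l_u = 0.31 m, l_f = 0.25 m (healthy-adult
range), shoulder 0.40 m above the robot origin, sensor mounted with Y
along the arm and Z along the arm-plane normal.

What the simulator does **not** model: dynamic (non-gravitational)
acceleration beyond the Gaussian noise term, sensor bias/scale errors,
soft-tissue artefact (sensor sliding on the arm), magnetometer/gyroscope
information, and robot-arm interaction forces. Passing the recovery tests
therefore demonstrates the correctness and noise robustness of the
geometry and the tracking loop, not immunity to every artefact of real
recordings.

## Numerical choices

- Angle wrapping to (−π, π] everywhere a difference of angles is formed
  (swivel error, swivel rate, metric differences).
- Swivel degeneracies (coincident S and W, elbow on the S–W line,
  reference axis parallel to S–W) raise typed errors; during tracking the
  previous swivel target is held for that step.
- Damped inverse with k² = 0 falls back to the exact inverse and raises on
  a singular matrix.
- Non-finite samples are skipped (with one warning) or abort the run,
  per configuration; accelerometer samples failing the 0.2 g gate hold
  the previous elbow estimate.
- Metrics: RMSE on wrapped differences; SD is the sample standard
  deviation (n−1) of the error series; angles reported in degrees,
  positions in centimetres; ROM is max − min per joint over the session.

## Validation battery and problem sizes

The acceptance script and suite validate, at 100 Hz with the default
geometry: (1) noiseless 60 s parameter recovery (per-joint RMSE well under
0.5°, elbow localization exact to ~1e-14 cm); (2) noisy recovery over five
60 s seeds with 0.01 g accelerometer noise and 1 cm unmodeled trunk sway
(per-joint RMSE a few degrees, per-joint Pearson R above 0.9); (3)
closed-form initial-pose recovery on 10³ random interior postures
(~1e-14 rad); (4) elbow-estimator contracts on 10⁴ random gravity
directions and 10³ postures (residuals ≲1e-12, selection 100%); (5)
Jacobian finite-difference agreement (≲1e-9) and the damped-inverse limit;
(6) stability under 5 cm shoulder steps across five seeds (finite,
continuous output).

## Known limitations

- **Swivel observability near vertical arm orientations.** When the
  shoulder-wrist axis comes within ~15° of the gravity direction, a
  rotation of the arm about that axis is nearly a rotation about gravity,
  which the accelerometer cannot see; the elbow estimate and hence q1–q3
  degrade there under noise (errors of ~5–15° in internal-external
  rotation for the stretches a session spends near that orientation).
  This is a physical limit of single-accelerometer sensing, not of the
  solver; planar therapy exercises keep the arm far from it.
- The closed-loop tracker is a local method: it needs the closed-form
  initialization and can lag by O(Δt²) curvature terms on fast motions.
- Joint limits are advisory during tracking; no constrained optimization
  is attempted.
- The accelerometer gate handles dynamic acceleration by rejection only;
  sustained fast motion starves the elbow estimator and the swivel target
  is held.
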