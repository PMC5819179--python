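# arm7ik

Seven-DoF upper-limb joint reconstruction for end-effector robot therapy,
from the robot's hand pose and **one** accelerometer on the upper arm.

End-effector rehabilitation robots hold the patient only at the hand, so
they measure the hand pose but say nothing about the posture of the rest
of the arm. Clinicians, however, assess recovery through joint-level
quantities such as per-joint range of motion. `arm7ik` closes that gap: it
reconstructs the seven anatomical joint angles of the arm — shoulder
abduction-adduction (q1), shoulder flexion-extension (q2),
internal-external rotation (q3), elbow flexion-extension (q4),
pronation-supination (q5), ulnar-radial deviation (q6) and wrist
flexion-extension (q7) — from three streams available in such a therapy:

- the robot end-effector pose (= wrist pose, robot frame),
- one upper-arm accelerometer sample per step (gravity direction, g units),
- the shoulder position (measured once at the start, or tracked).

## Method

The arm is a Denavit-Hartenberg chain of seven revolute joints with two
links, upper arm `l_u` and forearm `l_f`. A 7-DoF arm is redundant for a
6-DoF hand pose; the redundancy is the **swivel angle** α — the rotation of
the elbow about the shoulder-wrist axis, measured against a fixed
reference plane. Stacking the 1×7 swivel Jacobian under the 6×7 geometric
Jacobian gives the square **augmented Jacobian** J_A, and the joints are
tracked by closed-loop inverse kinematics,

```
q̇ = J*_A(q) { [v_d; α̇] + K·err },      q(t_k) = q(t_k-1) + q̇ Δt,
J*_A = J_Aᵀ (J_A J_Aᵀ + k² I)⁻¹        (damped least squares)
```

with the hand twist v_d and swivel rate α̇ finite-differenced from the
recorded streams and a proportional feedback K·err on the 7-row pose error
(position, axis-angle orientation, wrapped swivel).

The swivel target needs the elbow, which no robot sensor sees. It is
estimated from the accelerometer under a quasi-static assumption (the
sensor reads gravity only): the reading pins the sensor orientation down
to a rotation γ about gravity; requiring the sensor XY plane (which
contains the upper arm) to pass through the shoulder and wrist points
reduces γ to two roots, i.e. two mirrored elbow candidates; the anatomical
one is picked by the orientation of the arm-plane normal cross(EW, ES),
with forearm-length consistency and temporal continuity breaking the
postures where that rule is indeterminate.

The initial configuration is closed-form: the shoulder (q1–q3) and wrist
(q5–q7) spherical joints each give two atan2 branches from their rotation
blocks, q4 follows uniquely from the shoulder-wrist distance via the law
of cosines, and exactly one of the four branch combinations lies inside
the anatomical range [−π/2, π/2].

A synthetic-motion module simulates ground-truth joint trajectories and
all three sensor streams, so every stage is validated by parameter
recovery; see `docs/methods.md` for the model assumptions, parameter
defaults and known limitations.

## Worked example

Simulate a 20 s session at 100 Hz with realistic accelerometer noise
(0.01 g), then reconstruct it and compare with the simulated ground truth:

```sh
arm7ik simulate demo --duration 20 --seed 7 --accel-sigma 0.01
arm7ik init-pose demo/geometry.json demo/poses.csv demo/accel.csv demo/shoulder.csv
arm7ik reconstruct demo/geometry.json demo/poses.csv demo/accel.csv demo/shoulder.csv \
    --out demo/joints.csv --joints-true demo/joints_true.csv --metrics-out demo/metrics.json
```

`init-pose` prints the closed-form initial angles, e.g. `q0_deg = [19.11,
-16.38, 2.98, 31.37, 23.50, -10.68, 13.98]` for this seed. The
reconstruction metrics (`demo/metrics.json`) read:

```
rmse_deg  = [1.02, 1.30, 1.23, 0.05, 0.60, 1.09, 0.71]
pearson_r = [0.995, 0.998, 0.995, 1.000, 0.997, 0.990, 0.999]
elbow_rmse_cm = 0.86    wrist_rmse_cm = 0.72
rom_estimated_deg = [39.3, 28.2, 39.4, 14.7, 23.7, 31.1, 28.8]
rom_reference_deg = [35.0, 24.4, 35.8, 14.7, 22.3, 25.5, 27.6]
```

Per-joint errors stay near one degree under sensor noise, correlations are
≥0.99, and the session ranges of motion — the clinically reported
quantity — match the ground truth to a few degrees. The elbow and wrist
position RMSEs (here under 1 cm) are the forward-kinematics distances
between the reconstructed and true joint centres. Library users can do the
same in Python via `arm7ik.simulate_recording`,
`arm7ik.initial_pose_from_recording` and `arm7ik.reconstruct_trajectory`.

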