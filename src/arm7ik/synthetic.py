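"""Synthetic motion and sensor simulator.

Generates smooth ground-truth joint trajectories emulating slow
point-to-point reaching, and the three streams the reconstruction
consumes: end-effector poses (forward kinematics of the wrist), upper-arm
accelerometer samples (gravity direction rotated into the sensor frame —
the quasi-static model) and shoulder positions.  Every stage of the
pipeline is therefore testable by parameter recovery without recorded
data.

The accelerometer is rigid to the upper arm: its orientation is the
upper-arm (elbow) frame composed with the fixed mounting rotation, and the
gravity direction in the robot frame is the one implied by the reference
mounting, ``g_r = rR_acc0 @ (0, 1, 0)``, so the reference posture
reproduces the reference reading (0, 1, 0) by construction.

Shoulder drift emulates trunk compensation: the TRUE shoulder oscillates
(moving the simulated poses), while the recorded shoulder series keeps the
initially measured position — the algorithm's fixed-shoulder assumption is
violated exactly as in a real session.  ``inject_shoulder_steps``, by
contrast, shifts the recorded series itself to probe the tracker's
stability under discontinuous shoulder input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .arm_model import ArmGeometry, forward_kinematics
from .elbow_from_accel import ACC_REFERENCE_GRAVITY
from .session import SessionRecording
from .transforms import RigidTransform

__all__ = [
    "NoiseSpec",
    "SessionRecording",
    "REST_POSTURE",
    "default_geometry",
    "generate_joint_trajectory",
    "simulate_recording",
    "inject_shoulder_steps",
    "accelerometer_sample",
]

#: mid-range posture the trajectory generator oscillates about (rad);
#: elbow moderately flexed, all joints well inside the anatomical band and
#: away from the extended-arm and gimbal degeneracies
REST_POSTURE = np.array([0.30, -0.35, 0.25, 0.45, 0.20, -0.15, 0.10])

_MAX_JOINT_SPEED = 0.5   # rad/s, quasi-static regime
_RANGE_MARGIN = 0.1      # rad kept clear of the +-pi/2 band
_AMPLITUDE = 0.40        # rad, total per-joint oscillation at scale 1


@dataclass
class NoiseSpec:
    """Sensor and disturbance magnitudes for the simulator.

    accel_sigma (g), pose_sigma_pos (m), pose_sigma_rot (rad) are additive
    Gaussian; shoulder_drift_amplitude (m) drives a slow sinusoidal true-
    shoulder displacement.  All zero by default (noiseless).
    """

    accel_sigma: float = 0.0
    pose_sigma_pos: float = 0.0
    pose_sigma_rot: float = 0.0
    shoulder_drift_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("accel_sigma", "pose_sigma_pos", "pose_sigma_rot", "shoulder_drift_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def default_geometry(
    l_u: float = 0.31,
    l_f: float = 0.25,
    shoulder_position=(0.0, 0.40, 0.0),
) -> ArmGeometry:
    """Healthy-adult geometry with a consistent accelerometer mounting.

    The sensor sits on the upper arm with its Y axis pointing from the
    shoulder towards the elbow; the mounting rotation about the arm axis
    is chosen so that the sensor Z axis points along the arm-plane normal
    cross(EW, ES), the orientation the candidate-selection rule assumes.
    """
    base = ArmGeometry(l_u, l_f, RigidTransform(np.eye(3), np.asarray(shoulder_position, float)))
    R_f3_ref = forward_kinematics(np.zeros(7), base)[2].rotation
    mount_in_arm = Rotation.from_rotvec([0.0, 0.0, np.pi]).as_matrix()  # accel Y = -Y_arm
    return ArmGeometry(
        l_u,
        l_f,
        base.shoulder_pose,
        mount_ref_rotation=R_f3_ref @ mount_in_arm,
        elbow_in_accel_ref=mount_in_arm.T,
    )


def generate_joint_trajectory(
    duration_s: float,
    dt_s: float = 0.01,
    seed: int = 0,
    amplitude_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth per-joint sums of low-frequency sinusoids about the rest posture.

    Returns (t, q) with q of shape (n, 7), confined to
    (-pi/2 + 0.1, pi/2 - 0.1) with maximum joint speed <= 0.5 rad/s;
    deterministic given the seed.  ``amplitude_scale = 0`` yields the
    constant rest posture.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, dt_s)
    n_harm = 3
    freqs = rng.uniform(0.03, 0.12, size=(7, n_harm))       # Hz
    phases = rng.uniform(0.0, 2 * np.pi, size=(7, n_harm))
    weights = rng.uniform(0.3, 1.0, size=(7, n_harm))
    q = np.empty((len(t), 7))
    limit = np.pi / 2 - _RANGE_MARGIN
    for j in range(7):
        amp_total = _AMPLITUDE * amplitude_scale
        # keep within range...
        amp_total = min(amp_total, limit - abs(REST_POSTURE[j]))
        a = weights[j] / weights[j].sum() * amp_total
        # ...and within the quasi-static speed bound
        speed = float(np.sum(a * 2 * np.pi * freqs[j]))
        if speed > _MAX_JOINT_SPEED:
            a *= _MAX_JOINT_SPEED / speed
        q[:, j] = REST_POSTURE[j] + np.sum(
            a[None, :] * np.sin(2 * np.pi * freqs[j][None, :] * t[:, None] + phases[j][None, :]),
            axis=1,
        )
    return t, q


def _mount_in_arm_frame(geom: ArmGeometry) -> np.ndarray:
    """Mounting rotation of the sensor in upper-arm-frame coordinates."""
    R_f3_ref = forward_kinematics(np.zeros(7), geom)[2].rotation
    return R_f3_ref.T @ geom.mount_ref_rotation


def accelerometer_sample(q: np.ndarray, geom: ArmGeometry) -> np.ndarray:
    """Noise-free accelerometer reading at a posture (g units, sensor frame).

    The gravity direction implied by the reference mounting, rotated into
    the current sensor frame; equals (0, 1, 0) at the reference posture.
    """
    R_acc = forward_kinematics(q, geom)[2].rotation @ _mount_in_arm_frame(geom)
    return R_acc.T @ (geom.mount_ref_rotation @ ACC_REFERENCE_GRAVITY)


def simulate_recording(
    t: np.ndarray,
    q_series: np.ndarray,
    geom: ArmGeometry,
    noise: NoiseSpec | None = None,
) -> SessionRecording:
    """Sensor streams for a ground-truth joint trajectory.

    End-effector pose and accelerometer reading come from forward
    kinematics at the (possibly drifting) true shoulder; the recorded
    shoulder series stays at the initial position.  Ground truth joints
    are retained on the recording.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    t = np.asarray(t, dtype=float)
    q_series = np.asarray(q_series, dtype=float)
    n = len(t)
    if q_series.shape != (n, 7):
        raise ValueError("q_series must have shape (len(t), 7)")

    S0 = geom.shoulder_position.copy()
    if noise.shoulder_drift_amplitude > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        freq = rng.uniform(0.02, 0.08)
        phase = rng.uniform(0.0, 2 * np.pi)
        drift = noise.shoulder_drift_amplitude * np.sin(2 * np.pi * freq * t + phase)
        true_shoulder = S0[None, :] + drift[:, None] * direction[None, :]
    else:
        true_shoulder = np.tile(S0, (n, 1))

    mount = _mount_in_arm_frame(geom)
    g_r = geom.mount_ref_rotation @ ACC_REFERENCE_GRAVITY

    ee_R = np.empty((n, 3, 3))
    ee_p = np.empty((n, 3))
    accel = np.empty((n, 3))
    for k in range(n):
        gk = geom.with_shoulder_position(true_shoulder[k])
        frames = forward_kinematics(q_series[k], gk)
        ee_R[k] = frames[6].rotation
        ee_p[k] = frames[6].position
        accel[k] = (frames[2].rotation @ mount).T @ g_r

    if noise.accel_sigma > 0:
        accel = accel + rng.normal(0.0, noise.accel_sigma, size=accel.shape)
    if noise.pose_sigma_pos > 0:
        ee_p = ee_p + rng.normal(0.0, noise.pose_sigma_pos, size=ee_p.shape)
    if noise.pose_sigma_rot > 0:
        rv = rng.normal(0.0, noise.pose_sigma_rot, size=(n, 3))
        ee_R = Rotation.from_rotvec(rv).as_matrix() @ ee_R

    return SessionRecording(t, ee_R, ee_p, accel, np.tile(S0, (n, 1)), q_series.copy())


def inject_shoulder_steps(
    rec: SessionRecording,
    steps: list[tuple[float, np.ndarray]],
) -> SessionRecording:
    """Shift the recorded shoulder series by a displacement at given times.

    ``steps`` is a list of (time_s, 3-vector) pairs; each displacement
    (magnitude <= 0.1 m) applies from its time onward, cumulatively.  The
    end-effector poses are untouched (they are in the robot frame).
    """
    shoulder = rec.shoulder.copy()
    for time_s, step in steps:
        step = np.asarray(step, dtype=float).reshape(3)
        if np.linalg.norm(step) > 0.1:
            raise ValueError("shoulder step exceeds the 0.1 m bound")
        shoulder[rec.t >= time_s] += step
    return SessionRecording(
        rec.t.copy(), rec.ee_rotations.copy(), rec.ee_positions.copy(),
        rec.accel.copy(), shoulder,
        None if rec.q_true is None else rec.q_true.copy(),
    )
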