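"""Closed-form initial joint angles from the first recorded sample.

At the start of a session three poses are known in the robot frame: the
shoulder (measured once), the wrist (robot end-effector) and the elbow
(estimated from the accelerometer).  The shoulder spherical joint
(q1, q2, q3) and the wrist spherical joint (q5, q6, q7) each admit two
closed-form branches from the entries of their rotation blocks, while the
elbow flexion q4 follows uniquely from the shoulder-wrist distance via the
law of cosines.  Of the four branch combinations exactly one lies inside
the anatomical range [-pi/2, pi/2] for interior postures; that one is the
initial configuration.

The rotation-block entries n, o, a are the ROWS of the rotation matrix
(n_y = R[0,1], o_y = R[1,1], a_x = R[2,0], ...), matching the layout the
closed forms were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_model import JOINT_LIMIT, ArmGeometry, dh_table, dh_transform
from .transforms import RigidTransform, wrap_angle

__all__ = [
    "BranchSolution",
    "NoAnatomicalSolutionError",
    "shoulder_joint_candidates",
    "elbow_flexion_from_distance",
    "wrist_joint_candidates",
    "select_anatomical",
    "initial_joint_configuration",
]

_GIMBAL_EPS = 1e-9
_CLAMP_TOL = 1e-9


class NoAnatomicalSolutionError(ValueError):
    """No branch combination lies inside the anatomical joint range."""


@dataclass(frozen=True)
class BranchSolution:
    """One closed-form branch for a spherical-joint triple."""

    q_triple: tuple[float, float, float]
    branch_id: str  # "i", "ii", "iii" or "iv"
    degenerate: bool = False  # gimbal condition hit; free angle set to 0


def _noa(R: np.ndarray):
    # n, o, a rows of the rotation block
    n = R[0]
    o = R[1]
    a = R[2]
    return n, o, a


def shoulder_joint_candidates(T: RigidTransform) -> tuple[BranchSolution, BranchSolution]:
    """Both closed-form branches for (q1, q2, q3) from the shoulder block.

    Branch (i): q1 = atan2(-n_y, o_y), q2 = atan2(a_y, +sqrt(n_y^2+o_y^2)),
    q3 = atan2(a_z, -a_x).  Branch (ii) is the second atan2 root: the
    square root is negated, q3 flips both signs, and q1 shifts by pi.  At
    the gimbal condition (|q2| = pi/2, n_y = o_y = 0) q1 is set to 0 by
    convention and the branch flagged degenerate.
    """
    R = T.require_valid(1e-8).rotation
    n, o, a = _noa(R)
    ny, oy, ay = n[1], o[1], a[1]
    r = np.hypot(ny, oy)
    degenerate = r < _GIMBAL_EPS
    if degenerate:
        q1_i, q1_ii = 0.0, 0.0
    else:
        q1_i = np.arctan2(-ny, oy)
        q1_ii = wrap_angle(q1_i + np.pi)
    sol_i = BranchSolution(
        (float(q1_i), float(np.arctan2(ay, r)), float(np.arctan2(a[2], -a[0]))),
        "i",
        degenerate,
    )
    sol_ii = BranchSolution(
        (float(q1_ii), float(np.arctan2(ay, -r)), float(np.arctan2(-a[2], a[0]))),
        "ii",
        degenerate,
    )
    return sol_i, sol_ii


def elbow_flexion_from_distance(S: np.ndarray, W: np.ndarray, l_u: float, l_f: float) -> float:
    """Elbow flexion q4 from the shoulder-wrist distance (law of cosines).

    q4 = arcsin((l_u^2 + l_f^2 - ||W-S||^2) / (2 l_u l_f)), in
    [-pi/2, pi/2]; q4 = -pi/2 is the fully extended arm.  The arcsin
    argument is clamped within a 1e-9 tolerance; beyond that the limb
    lengths are inconsistent with the measured distance.
    """
    d2 = float(np.sum((np.asarray(W, float) - np.asarray(S, float)) ** 2))
    arg = (l_u**2 + l_f**2 - d2) / (2.0 * l_u * l_f)
    if abs(arg) > 1.0 + _CLAMP_TOL:
        raise ValueError(
            f"limb lengths inconsistent with wrist-shoulder distance (arcsin argument {arg:.6f})"
        )
    return float(np.arcsin(np.clip(arg, -1.0, 1.0)))


def wrist_joint_candidates(T47: RigidTransform) -> tuple[BranchSolution, BranchSolution]:
    """Both closed-form branches for (q5, q6, q7) from the wrist block.

    Branch (iii): q5 = -atan2(n_y, o_y), q6 = arcsin(a_y),
    q7 = -atan2(a_x, a_z); branch (iv) is the pi-complement of each.
    """
    R = T47.require_valid(1e-8).rotation
    n, o, a = _noa(R)
    ny, oy, ay = n[1], o[1], a[1]
    if abs(ay) > 1.0 + _CLAMP_TOL:
        raise ValueError("wrist rotation block entry a_y outside [-1, 1]")
    ay = float(np.clip(ay, -1.0, 1.0))
    degenerate = np.hypot(ny, oy) < _GIMBAL_EPS  # |q6| = pi/2
    q5_iii = 0.0 if degenerate else float(-np.arctan2(ny, oy))
    q6_iii = float(np.arcsin(ay))
    q7_iii = float(-np.arctan2(a[0], a[2]))
    sol_iii = BranchSolution((q5_iii, q6_iii, q7_iii), "iii", degenerate)
    # pi-complement branch: q5, q7 are pi minus the atan2 (= pi + the negated
    # angle of branch iii), q6 is pi minus the arcsin
    sol_iv = BranchSolution(
        (wrap_angle(np.pi + q5_iii), wrap_angle(np.pi - q6_iii), wrap_angle(np.pi + q7_iii)),
        "iv",
        degenerate,
    )
    return sol_iii, sol_iv


def select_anatomical(
    shoulder_candidates: tuple[BranchSolution, BranchSolution],
    q4: float,
    wrist_candidates: tuple[BranchSolution, BranchSolution],
    limit: float = JOINT_LIMIT,
) -> np.ndarray:
    """The unique branch combination inside the anatomical range.

    Of the four (shoulder x wrist) combinations, returns the one with all
    seven angles in [-limit, limit]; boundary ties are broken by the
    smallest sum of absolute angles.
    """
    tol = 1e-9
    feasible = []
    for sh in shoulder_candidates:
        for wr in wrist_candidates:
            q = np.array([*sh.q_triple, q4, *wr.q_triple])
            if np.all(np.abs(q) <= limit + tol):
                feasible.append(q)
    if not feasible:
        cands = [
            (sh.branch_id, wr.branch_id, (*sh.q_triple, q4, *wr.q_triple))
            for sh in shoulder_candidates
            for wr in wrist_candidates
        ]
        raise NoAnatomicalSolutionError(f"no anatomical solution among branches: {cands}")
    return min(feasible, key=lambda q: float(np.sum(np.abs(q))))


def initial_joint_configuration(
    elbow_pose: RigidTransform,
    wrist_pose: RigidTransform,
    geom: ArmGeometry,
) -> np.ndarray:
    """Initial seven joint angles from the first sample's three poses.

    The shoulder block is the elbow pose expressed in the arm base frame
    (base^T_3); the wrist block follows as (base^T_3 . A4)^{-1} base^T_7
    with A4 the elbow-flexion link transform.
    """
    base_inv = geom.shoulder_pose.inverse()
    T03 = base_inv @ elbow_pose
    T07 = base_inv @ wrist_pose
    shoulder = shoulder_joint_candidates(T03)
    q4 = elbow_flexion_from_distance(
        geom.shoulder_position, wrist_pose.position, geom.l_u, geom.l_f
    )
    A4 = dh_transform(dh_table(geom)[3], q4)
    T47 = (T03 @ A4).inverse() @ T07
    wrist = wrist_joint_candidates(T47)
    return select_anatomical(shoulder, q4, wrist)
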