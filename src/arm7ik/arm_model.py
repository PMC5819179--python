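"""Seven-DoF Denavit-Hartenberg model of the human arm.

The arm is modelled as a serial chain of seven revolute joints connected by
two links, the upper arm (length ``l_u``) and the forearm (``l_f``):

====  ===============================  ==============
q     movement                         joint group
====  ===============================  ==============
q1    shoulder abduction-adduction     shoulder
q2    shoulder flexion-extension       shoulder
q3    internal-external rotation       shoulder
q4    elbow flexion-extension          elbow
q5    pronation-supination             wrist
q6    ulnar-radial deviation           wrist
q7    wrist flexion-extension          wrist
====  ===============================  ==============

The DH table uses the classical (distal) convention: each link transform is
``Rz(theta) . Tz(d) . Tx(a) . Rx(alpha)`` with ``theta = offset + q_i``.
Angles are radians, lengths metres.  Anatomical joint ranges are the soft
band [-pi/2, pi/2]; they are warned about, never clamped, during tracking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .transforms import RigidTransform

__all__ = [
    "DHRow",
    "ArmGeometry",
    "dh_table",
    "dh_transform",
    "forward_kinematics",
    "joint_points",
    "check_joint_limits",
    "JOINT_NAMES",
    "JOINT_LIMIT",
]

JOINT_NAMES = (
    "shoulder_abduction_adduction",
    "shoulder_flexion_extension",
    "internal_external_rotation",
    "elbow_flexion_extension",
    "pronation_supination",
    "ulnar_radial_deviation",
    "wrist_flexion_extension",
)

#: soft anatomical limit (rad), symmetric about zero for every joint
JOINT_LIMIT = np.pi / 2

_THETA_OFFSETS = (np.pi / 2, 3 * np.pi / 2, 0.0, np.pi / 2, np.pi / 2, np.pi / 2, np.pi / 2)
_ALPHAS = (np.pi / 2, np.pi / 2, -np.pi / 2, np.pi / 2, np.pi / 2, np.pi / 2, np.pi / 2)


@dataclass(frozen=True)
class DHRow:
    """One row of the DH table."""

    theta_offset: float
    d: float
    a: float
    alpha: float
    joint_index: int  # 1..7


@dataclass
class ArmGeometry:
    """Subject-specific arm geometry and sensor mounting.

    Parameters
    ----------
    l_u, l_f
        Upper-arm and forearm lengths (m).  Measured from the lateral side
        of the acromion to the proximal radius head, and from there to the
        radial styloid.
    shoulder_pose
        Pose of the arm base frame (shoulder centre) in the robot frame.
    mount_ref_rotation
        Orientation of the upper-arm accelerometer in the robot frame at
        the reference posture (all joints zero); its Y axis points from the
        shoulder towards the elbow.
    elbow_in_accel_ref
        Rotation of the elbow (upper-arm) frame expressed in the
        accelerometer frame at the reference posture.
    """

    l_u: float
    l_f: float
    shoulder_pose: RigidTransform = field(default_factory=RigidTransform.identity)
    mount_ref_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    elbow_in_accel_ref: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.mount_ref_rotation = np.asarray(self.mount_ref_rotation, dtype=float)
        self.elbow_in_accel_ref = np.asarray(self.elbow_in_accel_ref, dtype=float)
        for name in ("l_u", "l_f"):
            v = getattr(self, name)
            if not 0.1 < v < 0.6:
                raise ValueError(f"{name}={v} m outside the (0.1, 0.6) m sanity band")
        for name in ("mount_ref_rotation", "elbow_in_accel_ref"):
            R = getattr(self, name)
            if not (np.allclose(R.T @ R, np.eye(3), atol=1e-8) and np.linalg.det(R) > 0):
                raise ValueError(f"{name} is not a proper rotation")
        self.shoulder_pose.require_valid(1e-8)

    @property
    def shoulder_position(self) -> np.ndarray:
        return self.shoulder_pose.position

    def with_shoulder_position(self, p: np.ndarray) -> "ArmGeometry":
        """Copy of the geometry with the shoulder translated to ``p``."""
        g = ArmGeometry.__new__(ArmGeometry)
        g.l_u, g.l_f = self.l_u, self.l_f
        g.shoulder_pose = RigidTransform(self.shoulder_pose.rotation, np.asarray(p, float))
        g.mount_ref_rotation = self.mount_ref_rotation
        g.elbow_in_accel_ref = self.elbow_in_accel_ref
        return g

    # -- config I/O ----------------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path) -> "ArmGeometry":
        """Load geometry from a JSON or YAML config file.

        Required keys: ``l_u``, ``l_f``, ``shoulder_position`` (3 floats, m).
        Optional: ``shoulder_quaternion``, ``mount_ref_quaternion``,
        ``elbow_ref_quaternion`` — unit quaternions in (w, x, y, z) order,
        defaulting to identity.
        """
        path = Path(path)
        text = path.read_text()
        cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(cfg)

    @classmethod
    def from_dict(cls, cfg: dict) -> "ArmGeometry":
        for key in ("l_u", "l_f", "shoulder_position"):
            if key not in cfg:
                raise KeyError(f"geometry config missing required key '{key}'")

        def quat(key):
            if key not in cfg:
                return np.eye(3)
            w, x, y, z = cfg[key]
            return Rotation.from_quat([x, y, z, w]).as_matrix()

        return cls(
            l_u=float(cfg["l_u"]),
            l_f=float(cfg["l_f"]),
            shoulder_pose=RigidTransform(quat("shoulder_quaternion"), np.asarray(cfg["shoulder_position"], float)),
            mount_ref_rotation=quat("mount_ref_quaternion"),
            elbow_in_accel_ref=quat("elbow_ref_quaternion"),
        )

    def to_dict(self) -> dict:
        def quat(R):
            x, y, z, w = Rotation.from_matrix(R).as_quat()
            return [float(w), float(x), float(y), float(z)]

        return {
            "l_u": self.l_u,
            "l_f": self.l_f,
            "shoulder_position": [float(v) for v in self.shoulder_position],
            "shoulder_quaternion": quat(self.shoulder_pose.rotation),
            "mount_ref_quaternion": quat(self.mount_ref_rotation),
            "elbow_ref_quaternion": quat(self.elbow_in_accel_ref),
        }


def dh_table(geom: ArmGeometry) -> list[DHRow]:
    """The seven DH rows of the arm for a given geometry."""
    d = (0.0, 0.0, geom.l_u, 0.0, geom.l_f, 0.0, 0.0)
    return [
        DHRow(_THETA_OFFSETS[i], d[i], 0.0, _ALPHAS[i], i + 1)
        for i in range(7)
    ]


def dh_transform(row: DHRow, q_i: float) -> RigidTransform:
    """Link transform for joint value ``q_i`` (classical DH convention)."""
    th = row.theta_offset + q_i
    ct, st = np.cos(th), np.sin(th)
    ca, sa = np.cos(row.alpha), np.sin(row.alpha)
    R = np.array(
        [
            [ct, -st * ca, st * sa],
            [st, ct * ca, -ct * sa],
            [0.0, sa, ca],
        ]
    )
    p = np.array([row.a * ct, row.a * st, row.d])
    return RigidTransform(R, p)


def forward_kinematics(q: np.ndarray, geom: ArmGeometry) -> list[RigidTransform]:
    """Cumulative frames of the chain in the robot frame.

    Returns the seven cumulative transforms ``rT_s . A1 ... Ak``; index 2
    (frame 3) is the elbow frame at the end of the upper arm, index 6
    (frame 7) the hand pose ``rT_w``.
    """
    q = np.asarray(q, dtype=float).reshape(7)
    T = geom.shoulder_pose
    out = []
    for row in dh_table(geom):
        T = T @ dh_transform(row, q[row.joint_index - 1])
        out.append(T)
    return out


def joint_points(q: np.ndarray, geom: ArmGeometry) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shoulder, elbow and wrist points (robot frame, m)."""
    frames = forward_kinematics(q, geom)
    return geom.shoulder_position, frames[2].position, frames[4].position


def check_joint_limits(q: np.ndarray, limit: float = JOINT_LIMIT, warn: bool = True) -> np.ndarray:
    """Boolean mask of joints outside the soft anatomical band.

    Emits a single warning naming the offending joints when ``warn``.
    """
    q = np.asarray(q, dtype=float).reshape(7)
    out = np.abs(q) > limit
    if warn and out.any():
        names = ", ".join(JOINT_NAMES[i] for i in np.flatnonzero(out))
        warnings.warn(f"joints outside anatomical range: {names}", stacklevel=2)
    return out
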