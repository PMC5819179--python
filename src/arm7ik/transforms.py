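"""Rigid transforms and small rotation utilities.

All rotations are 3x3 proper orthonormal matrices, positions are metres.
The conversions to/from quaternions and axis-angle go through
:class:`scipy.spatial.transform.Rotation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "skew",
    "rotation_about_axis",
    "rotation_log",
    "wrap_angle",
]

_ORTHO_TOL = 1e-10


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ u == cross(v, u)."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation by ``angle`` about the unit vector ``axis``."""
    k = skew(np.asarray(axis, dtype=float))
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def rotation_log(R: np.ndarray) -> np.ndarray:
    """Axis-angle vector (rotation vector) of a rotation matrix."""
    return Rotation.from_matrix(R).as_rotvec()


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    wrapped = np.mod(-a + np.pi, 2.0 * np.pi)
    out = -(wrapped - np.pi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RigidTransform:
    """Homogeneous rigid-body transform (rotation + translation)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, T: np.ndarray) -> "RigidTransform":
        T = np.asarray(T, dtype=float)
        return cls(T[:3, :3].copy(), T[:3, 3].copy())

    # -- algebra ------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        T = np.eye(4)
        T[:3, :3] = self.rotation
        T[:3, 3] = self.position
        return T

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.position + self.position,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.position)

    def transform_point(self, p: np.ndarray) -> np.ndarray:
        return self.rotation @ np.asarray(p, dtype=float) + self.position

    # -- validation ---------------------------------------------------
    def is_valid(self, tol: float = _ORTHO_TOL) -> bool:
        R = self.rotation
        return (
            np.allclose(R.T @ R, np.eye(3), atol=tol)
            and abs(np.linalg.det(R) - 1.0) < tol
            and bool(np.all(np.isfinite(self.position)))
        )

    def require_valid(self, tol: float = _ORTHO_TOL) -> "RigidTransform":
        if not self.is_valid(tol):
            raise ValueError("rotation is not orthonormal with determinant +1")
        return self
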