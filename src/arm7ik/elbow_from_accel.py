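"""Elbow localization from a single upper-arm accelerometer.

Under the quasi-static assumption the accelerometer reads only the gravity
direction, so its sample is a unit vector ``accV_g`` in the sensor frame.
Relative to the reference reading ``acc0V_g = (0, 1, 0)`` (arm hanging, Y
axis of the sensor pointing along gravity), the sample constrains the
sensor orientation up to a rotation about gravity.  The missing rotation
angle (gamma) is pinned down by requiring the sensor XY plane, which
contains the upper arm, to pass through the known shoulder and wrist
points; this yields two candidate elbow positions mirrored through the
shoulder-wrist plane, disambiguated by the orientation of the arm-plane
normal cross(EW, ES).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm_model import ArmGeometry
from .transforms import RigidTransform, rotation_about_axis, skew

__all__ = [
    "ACC_REFERENCE_GRAVITY",
    "DegenerateGeometryError",
    "InconsistentSensorError",
    "GravityRotation",
    "ElbowCandidates",
    "normalize_sample",
    "gravity_rotation",
    "solve_gamma",
    "elbow_candidates",
    "select_elbow",
    "elbow_pose",
    "estimate_elbow",
]

#: normalized accelerometer reading at the reference posture (g units)
ACC_REFERENCE_GRAVITY = np.array([0.0, 1.0, 0.0])

#: quasi-static gate: reject samples whose magnitude departs from 1 g by more
_NORM_GATE = 0.2

_SIN_EPS = 1e-8


class DegenerateGeometryError(ValueError):
    """Shoulder, elbow and wrist are collinear (or coincident)."""


class InconsistentSensorError(ValueError):
    """No sensor orientation satisfies both gravity and plane constraints."""


@dataclass(frozen=True)
class GravityRotation:
    """Minimal rotation aligning the current sample with the reference.

    ``R_tilde`` satisfies ``R_tilde @ accV_g == acc0V_g``: it maps the
    measured gravity direction back to the reference reading.  Any sensor
    orientation compatible with the sample is ``rot(acc0V_g, gamma) @
    R_tilde`` for some gamma.
    """

    R_tilde: np.ndarray
    theta: float
    axis: np.ndarray


@dataclass(frozen=True)
class ElbowCandidates:
    """The two plane-consistent accelerometer poses and elbow points."""

    gamma_pair: tuple[float, float]
    poses: tuple[RigidTransform, RigidTransform]  # rT_acc per candidate
    elbow_points: tuple[np.ndarray, np.ndarray]   # rP_e per candidate


def normalize_sample(v: np.ndarray) -> np.ndarray:
    """Validate the quasi-static gate and return the unit gravity direction.

    Raises
    ------
    InconsistentSensorError
        If the sample magnitude departs from 1 g by more than 0.2 g,
        indicating non-negligible dynamic acceleration.
    """
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or abs(n - 1.0) > _NORM_GATE:
        raise InconsistentSensorError(f"accelerometer magnitude {n:.3f} g fails the quasi-static gate")
    return v / n


def gravity_rotation(sample: np.ndarray) -> GravityRotation:
    """Rotation aligning the measured gravity direction with the reference.

    Built from the Rodrigues form ``I + M + M^2 (1-cos)/sin^2`` on the axis
    ``V = acc0V_g x accV_g``, oriented so that the returned matrix maps the
    sample onto the reference reading.  The antiparallel sample (arm
    upside-down) falls outside the Rodrigues form and is handled as an
    explicit 180-degree rotation about X; a near-zero rotation returns the
    identity.
    """
    g0 = ACC_REFERENCE_GRAVITY
    v = normalize_sample(sample)
    V = np.cross(g0, v)
    sin_t = np.linalg.norm(V)
    cos_t = float(g0 @ v)
    if sin_t < _SIN_EPS:
        if cos_t > 0.0:  # sample already at reference
            return GravityRotation(np.eye(3), 0.0, np.array([0.0, 0.0, 1.0]))
        # antiparallel: 180 deg about any axis perpendicular to g0
        axis = np.array([1.0, 0.0, 0.0])
        return GravityRotation(rotation_about_axis(axis, np.pi), np.pi, axis)
    M = skew(V)
    R = np.eye(3) + M + M @ M * (1.0 - cos_t) / sin_t**2
    # R maps g0 -> v; the alignment contract wants v -> g0, hence transpose
    return GravityRotation(R.T, float(np.arctan2(sin_t, cos_t)), V / sin_t)


def solve_gamma(rot: GravityRotation, S: np.ndarray, W: np.ndarray, geom: ArmGeometry) -> tuple[float, float]:
    """Angles about gravity making the sensor XY plane contain S and W.

    The candidate sensor orientation is ``rot(g0, gamma) @ R_tilde`` with
    ``g0`` the gravity direction in the reference sensor frame; its Z axis
    mapped to the robot frame must be orthogonal to W - S.  This reduces to
    ``a cos(gamma) + b sin(gamma) + c = 0``, returning both roots.
    """
    S = np.asarray(S, float)
    W = np.asarray(W, float)
    sw = W - S
    nsw = np.linalg.norm(sw)
    if nsw < 1e-9:
        raise DegenerateGeometryError("shoulder and wrist coincide")
    g0 = ACC_REFERENCE_GRAVITY
    u = rot.R_tilde @ np.array([0.0, 0.0, 1.0])          # candidate Z at gamma = 0
    w = geom.mount_ref_rotation.T @ (sw / nsw)           # target direction, sensor-ref frame
    a = float(u @ w - (g0 @ u) * (g0 @ w))
    b = float(np.cross(g0, u) @ w)
    c = float((g0 @ u) * (g0 @ w))
    amp = np.hypot(a, b)
    if abs(c) > amp + 1e-12:
        raise InconsistentSensorError(
            "accelerometer reading inconsistent with the shoulder-wrist geometry"
        )
    phi = np.arctan2(b, a)
    delta = np.arccos(np.clip(-c / amp, -1.0, 1.0)) if amp > 0 else 0.0
    return float(phi + delta), float(phi - delta)


def elbow_candidates(
    gammas: tuple[float, float],
    rot: GravityRotation,
    S: np.ndarray,
    geom: ArmGeometry,
) -> ElbowCandidates:
    """Accelerometer poses and elbow points for both gamma roots.

    Each candidate pose has rotation ``rR_acc0 . rot(g0, gamma) . R_tilde``
    and position at the shoulder; the elbow sits at ``l_u`` along the
    sensor Y axis.
    """
    S = np.asarray(S, float)
    g0 = ACC_REFERENCE_GRAVITY
    poses, elbows = [], []
    for g in gammas:
        R_acc = geom.mount_ref_rotation @ rotation_about_axis(g0, g) @ rot.R_tilde
        T = RigidTransform(R_acc, S)
        poses.append(T)
        elbows.append(T.transform_point([0.0, geom.l_u, 0.0]))
    return ElbowCandidates((float(gammas[0]), float(gammas[1])), (poses[0], poses[1]), (elbows[0], elbows[1]))


def select_elbow(
    cands: ElbowCandidates,
    S: np.ndarray,
    W: np.ndarray,
    prev_elbow: np.ndarray | None = None,
    l_f: float | None = None,
) -> int:
    """Index (0 or 1) of the anatomically correct candidate.

    The primary rule: the correct sensor Z axis points along the
    arm-plane normal cross(W - E, S - E).  Because each candidate's
    S, E, W triangle lies in that candidate's own sensor plane, each dot
    product is exactly +-1, and the rule is indeterminate whenever the
    mirrored candidate has crossed the shoulder-wrist line (both dots
    +1).  The tie is then broken by forearm-length consistency
    (|dist(W, E) - l_f| smallest) when ``l_f`` is given — only the true
    candidate also closes the forearm triangle — falling back to
    continuity with ``prev_elbow``, then to the larger dot.  Raises on a
    collinear (extended-arm) geometry where every candidate normal
    vanishes; callers should then hold the previous selection.
    """
    S = np.asarray(S, float)
    W = np.asarray(W, float)
    dots: dict[int, float] = {}
    for i in (0, 1):
        E = cands.elbow_points[i]
        n = np.cross(W - E, S - E)
        nn = np.linalg.norm(n)
        if nn < 1e-9 * max(np.linalg.norm(W - E), 1e-12):
            continue
        z = cands.poses[i].rotation[:, 2]
        dots[i] = float(z @ n / nn)
    positive = [i for i, d in dots.items() if d > 1e-9]
    if len(positive) == 1:
        return positive[0]
    if len(positive) == 2:
        if l_f is not None:
            mism = {i: abs(np.linalg.norm(W - cands.elbow_points[i]) - l_f) for i in positive}
            # near-symmetric postures leave the forearm check undecided too
            if abs(mism[0] - mism[1]) > 1e-3 or prev_elbow is None:
                return min(positive, key=lambda i: mism[i])
        if prev_elbow is not None:
            prev_elbow = np.asarray(prev_elbow, float)
            return min(positive, key=lambda i: np.linalg.norm(cands.elbow_points[i] - prev_elbow))
        return max(positive, key=lambda i: dots[i])
    raise DegenerateGeometryError("shoulder, elbow and wrist collinear; selection undefined")


def elbow_pose(candidate: RigidTransform, geom: ArmGeometry) -> RigidTransform:
    """Elbow pose ``rT_e`` from the selected accelerometer pose.

    The elbow rotation composes the sensor orientation with the fixed
    elbow-in-sensor mounting rotation; the position is the candidate elbow
    point.
    """
    R_e = candidate.rotation @ geom.elbow_in_accel_ref
    P_e = candidate.transform_point([0.0, geom.l_u, 0.0])
    return RigidTransform(R_e, P_e)


def estimate_elbow(
    sample: np.ndarray,
    S: np.ndarray,
    W: np.ndarray,
    geom: ArmGeometry,
    prev_elbow: np.ndarray | None = None,
) -> tuple[RigidTransform, int]:
    """Full elbow estimate from one accelerometer sample.

    Chains gravity alignment, the gamma plane constraint, candidate
    construction and selection.  ``prev_elbow`` (the previous step's
    elbow point) breaks selection ties and stands in for the selection
    rule on a collinear S, E, W geometry.

    Returns the elbow pose and the selected candidate index.
    """
    rot = gravity_rotation(sample)
    gammas = solve_gamma(rot, S, W, geom)
    cands = elbow_candidates(gammas, rot, S, geom)
    try:
        idx = select_elbow(cands, S, W, prev_elbow, geom.l_f)
    except DegenerateGeometryError:
        if prev_elbow is None:
            raise
        idx = int(
            np.argmin([np.linalg.norm(e - np.asarray(prev_elbow, float)) for e in cands.elbow_points])
        )
    return elbow_pose(cands.poses[idx], geom), idx
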