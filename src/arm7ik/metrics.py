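"""Session evaluation: RMSE, SD, Pearson correlation and range of motion.

Angles are handled on wrapped differences in (-pi, pi] and reported in
degrees; positions are reported in centimetres.  SD follows the sample
convention (n - 1 denominator) on the error series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .arm_model import ArmGeometry, forward_kinematics
from .transforms import wrap_angle

__all__ = ["JointMetrics", "RomReport", "rmse_sd", "pearson_r", "rom", "joint_metrics"]


@dataclass(frozen=True)
class JointMetrics:
    """Per-joint accuracy of a reconstruction against a reference."""

    rmse_deg: np.ndarray        # (7,)
    sd_deg: np.ndarray          # (7,)
    pearson: np.ndarray         # (7,)
    significant: np.ndarray     # (7,) bool, p < 0.05
    elbow_rmse_cm: float | None = None
    wrist_rmse_cm: float | None = None

    def to_dict(self) -> dict:
        out = {
            "rmse_deg": [float(v) for v in self.rmse_deg],
            "sd_deg": [float(v) for v in self.sd_deg],
            "pearson_r": [float(v) for v in self.pearson],
            "significant": [bool(v) for v in self.significant],
        }
        if self.elbow_rmse_cm is not None:
            out["elbow_rmse_cm"] = float(self.elbow_rmse_cm)
        if self.wrist_rmse_cm is not None:
            out["wrist_rmse_cm"] = float(self.wrist_rmse_cm)
        return out


@dataclass(frozen=True)
class RomReport:
    """Per-joint range of motion (max - min) over a session, degrees."""

    rom_deg: np.ndarray

    def __post_init__(self):
        if np.any(self.rom_deg < 0):
            raise ValueError("range of motion cannot be negative")


def _diffs(estimated: np.ndarray, reference: np.ndarray, angular: bool) -> np.ndarray:
    estimated = np.asarray(estimated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if estimated.shape != reference.shape:
        raise ValueError(f"series shapes differ: {estimated.shape} vs {reference.shape}")
    if len(estimated) < 2:
        raise ValueError("need at least two samples")
    d = estimated - reference
    return wrap_angle(d) if angular else d


def rmse_sd(estimated, reference, angular: bool = True):
    """Root-mean-square error and sample SD of the error, per column."""
    d = _diffs(estimated, reference, angular)
    return np.sqrt(np.mean(d**2, axis=0)), np.std(d, axis=0, ddof=1)


def pearson_r(estimated, reference):
    """Product-moment correlation (and p-value) per column.

    Raises on a constant series, where the correlation is undefined.
    """
    estimated = np.atleast_2d(np.asarray(estimated, dtype=float).T).T
    reference = np.atleast_2d(np.asarray(reference, dtype=float).T).T
    if estimated.shape != reference.shape:
        raise ValueError("series shapes differ")
    r = np.empty(estimated.shape[1])
    p = np.empty(estimated.shape[1])
    for j in range(estimated.shape[1]):
        if np.ptp(estimated[:, j]) == 0 or np.ptp(reference[:, j]) == 0:
            raise ValueError(f"correlation undefined for constant series (column {j})")
        r[j], p[j] = stats.pearsonr(estimated[:, j], reference[:, j])
    return r, p


def rom(q_series: np.ndarray) -> RomReport:
    """Range of motion per joint over the session (degrees)."""
    q_series = np.asarray(q_series, dtype=float)
    if q_series.size == 0:
        raise ValueError("empty series")
    return RomReport(np.degrees(np.ptp(q_series, axis=0)))


def joint_metrics(
    estimated_q: np.ndarray,
    reference_q: np.ndarray,
    geom: ArmGeometry | None = None,
) -> JointMetrics:
    """Full per-joint accuracy report.

    With a geometry, also reports elbow and wrist position RMSE (cm) by
    pushing both joint series through forward kinematics.
    """
    rmse, sd = rmse_sd(estimated_q, reference_q, angular=True)
    r, p = pearson_r(estimated_q, reference_q)
    elbow = wrist = None
    if geom is not None:
        d_e = np.empty(len(estimated_q))
        d_w = np.empty(len(estimated_q))
        for k in range(len(estimated_q)):
            fe = forward_kinematics(estimated_q[k], geom)
            fr = forward_kinematics(reference_q[k], geom)
            d_e[k] = np.linalg.norm(fe[2].position - fr[2].position)
            d_w[k] = np.linalg.norm(fe[4].position - fr[4].position)
        elbow = 100.0 * float(np.sqrt(np.mean(d_e**2)))
        wrist = 100.0 * float(np.sqrt(np.mean(d_w**2)))
    return JointMetrics(np.degrees(rmse), np.degrees(sd), r, p < 0.05, elbow, wrist)
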