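"""Whole-session orchestration: initial pose, tracking, metrics."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import io
from .arm_model import ArmGeometry
from .elbow_from_accel import estimate_elbow
from .initial_pose import initial_joint_configuration
from .metrics import joint_metrics, rom
from .session import SessionRecording
from .swivel_ik import IKConfig, ReconstructionResult, reconstruct_trajectory
from .transforms import RigidTransform

__all__ = ["initial_pose_from_recording", "run_session"]

log = logging.getLogger("arm7ik")


def initial_pose_from_recording(rec: SessionRecording, geom: ArmGeometry) -> np.ndarray:
    """Closed-form initial joints from the first sample of a recording."""
    geom0 = geom.with_shoulder_position(rec.shoulder[0])
    wrist_pose = RigidTransform(rec.ee_rotations[0], rec.ee_positions[0])
    elbow_pose, _ = estimate_elbow(rec.accel[0], rec.shoulder[0], rec.ee_positions[0], geom0)
    return initial_joint_configuration(elbow_pose, wrist_pose, geom0)


def run_session(
    poses_path: str | Path,
    accel_path: str | Path,
    shoulder_path: str | Path,
    geometry_config: str | Path,
    out_joints: str | Path,
    joints_true_path: str | Path | None = None,
    ik_config: IKConfig | None = None,
    out_metrics: str | Path | None = None,
) -> tuple[ReconstructionResult, dict | None]:
    """Reconstruct one session from its CSV files.

    Runs the closed-form initialization on the first sample, tracks the
    whole recording, writes the joint CSV (with diagnostics columns) and,
    when ground truth is available, a metrics JSON.
    """
    geom = ArmGeometry.from_config(geometry_config)
    cfg = ik_config or IKConfig()
    rec = io.read_recording(poses_path, accel_path, shoulder_path, joints_true_path)

    q0 = initial_pose_from_recording(rec, geom)
    log.info("initial pose (deg): %s", np.round(np.degrees(q0), 2).tolist())

    result = reconstruct_trajectory(rec, geom, cfg, q0)
    if result.n_skipped:
        log.warning("skipped %d non-finite samples", result.n_skipped)
    if result.n_gated:
        log.warning("held elbow estimate on %d gated/degenerate samples", result.n_gated)
    if result.n_limit_warnings:
        log.warning("%d steps outside the anatomical joint range", result.n_limit_warnings)

    io.write_joints(
        out_joints,
        result.t,
        result.q,
        diagnostics={
            "pose_error_norm": result.pose_error_norm,
            "condition_number": result.condition_number,
        },
    )

    report = None
    if rec.q_true is not None:
        # metrics are computed on the samples that were actually tracked
        n = len(result.t)
        ref_q = rec.q_true[np.isin(rec.t, result.t)]
        m = joint_metrics(result.q, ref_q, geom)
        report = {
            "joints": m.to_dict(),
            "rom_estimated_deg": rom(result.q).rom_deg.tolist(),
            "rom_reference_deg": rom(rec.q_true).rom_deg.tolist(),
            "n_samples": n,
        }
        if out_metrics is not None:
            Path(out_metrics).write_text(json.dumps(report, indent=2))
    return result, report
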