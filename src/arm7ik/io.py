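"""CSV serialization of recordings and joint trajectories.

All files are comma-separated with a '.' decimal and a header row.
Orientations are stored as unit quaternions in (w, x, y, z) order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .session import SessionRecording

__all__ = [
    "POSES_COLUMNS",
    "ACCEL_COLUMNS",
    "SHOULDER_COLUMNS",
    "JOINT_COLUMNS",
    "write_recording",
    "read_recording",
    "write_joints",
    "read_joints",
]

POSES_COLUMNS = ["time_s", "px", "py", "pz", "qw", "qx", "qy", "qz"]
ACCEL_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]
SHOULDER_COLUMNS = ["time_s", "sx", "sy", "sz"]
JOINT_COLUMNS = ["time_s"] + [f"q{i}_rad" for i in range(1, 8)]


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df[columns]


def write_recording(rec: SessionRecording, out_dir: str | Path) -> dict[str, Path]:
    """Write a recording as paired CSVs; returns the paths written.

    Files: poses.csv, accel.csv, shoulder.csv and, when ground truth is
    present, joints_true.csv.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    quat = Rotation.from_matrix(rec.ee_rotations).as_quat()  # (x, y, z, w)
    poses = pd.DataFrame(
        np.column_stack([rec.t, rec.ee_positions, quat[:, [3, 0, 1, 2]]]),
        columns=POSES_COLUMNS,
    )
    accel = pd.DataFrame(np.column_stack([rec.t, rec.accel]), columns=ACCEL_COLUMNS)
    shoulder = pd.DataFrame(np.column_stack([rec.t, rec.shoulder]), columns=SHOULDER_COLUMNS)
    paths = {
        "poses": out_dir / "poses.csv",
        "accel": out_dir / "accel.csv",
        "shoulder": out_dir / "shoulder.csv",
    }
    poses.to_csv(paths["poses"], index=False)
    accel.to_csv(paths["accel"], index=False)
    shoulder.to_csv(paths["shoulder"], index=False)
    if rec.q_true is not None:
        paths["joints_true"] = out_dir / "joints_true.csv"
        write_joints(paths["joints_true"], rec.t, rec.q_true)
    return paths


def read_recording(
    poses_path: str | Path,
    accel_path: str | Path,
    shoulder_path: str | Path,
    joints_path: str | Path | None = None,
) -> SessionRecording:
    """Assemble a recording from its CSV files (lengths must agree)."""
    poses = _read_csv(poses_path, POSES_COLUMNS)
    accel = _read_csv(accel_path, ACCEL_COLUMNS)
    shoulder = _read_csv(shoulder_path, SHOULDER_COLUMNS)
    if not (len(poses) == len(accel) == len(shoulder)):
        raise ValueError(
            f"stream lengths differ: poses={len(poses)}, accel={len(accel)}, shoulder={len(shoulder)}"
        )
    quat = poses[["qx", "qy", "qz", "qw"]].to_numpy()
    rot = Rotation.from_quat(quat).as_matrix()
    q_true = None
    if joints_path is not None:
        _, q_true = read_joints(joints_path)
    return SessionRecording(
        poses["time_s"].to_numpy(),
        rot,
        poses[["px", "py", "pz"]].to_numpy(),
        accel[["ax_g", "ay_g", "az_g"]].to_numpy(),
        shoulder[["sx", "sy", "sz"]].to_numpy(),
        q_true,
    )


def write_joints(
    path: str | Path,
    t: np.ndarray,
    q: np.ndarray,
    diagnostics: dict[str, np.ndarray] | None = None,
) -> Path:
    """Joint trajectory CSV: time_s, q1_rad..q7_rad (+ diagnostics columns)."""
    path = Path(path)
    df = pd.DataFrame(np.column_stack([t, q]), columns=JOINT_COLUMNS)
    for name, series in (diagnostics or {}).items():
        df[name] = series
    df.to_csv(path, index=False)
    return path


def read_joints(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a joint trajectory CSV; returns (t, q)."""
    df = _read_csv(path, JOINT_COLUMNS)
    return df["time_s"].to_numpy(), df[JOINT_COLUMNS[1:]].to_numpy()
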