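"""Synchronized recording of one therapy session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SessionRecording"]


@dataclass
class SessionRecording:
    """Time series the reconstruction consumes, at a nominal 100 Hz.

    Attributes
    ----------
    t : (n,) strictly increasing timestamps (s)
    ee_rotations : (n, 3, 3) end-effector orientations in the robot frame
    ee_positions : (n, 3) end-effector positions (m)
    accel : (n, 3) upper-arm accelerometer samples (g units, sensor frame)
    shoulder : (n, 3) shoulder positions (m)
    q_true : optional (n, 7) ground-truth joints (rad), kept by the simulator
    """

    t: np.ndarray
    ee_rotations: np.ndarray
    ee_positions: np.ndarray
    accel: np.ndarray
    shoulder: np.ndarray
    q_true: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.ee_rotations = np.asarray(self.ee_rotations, dtype=float)
        self.ee_positions = np.asarray(self.ee_positions, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.shoulder = np.asarray(self.shoulder, dtype=float)
        n = len(self.t)
        for name in ("ee_rotations", "ee_positions", "accel", "shoulder"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from timestamps ({n})")
        if self.q_true is not None:
            self.q_true = np.asarray(self.q_true, dtype=float)
            if len(self.q_true) != n:
                raise ValueError("q_true length differs from timestamps")
        if n >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def take(self, idx: np.ndarray) -> "SessionRecording":
        """Sub-recording at the given sample indices."""
        return SessionRecording(
            self.t[idx],
            self.ee_rotations[idx],
            self.ee_positions[idx],
            self.accel[idx],
            self.shoulder[idx],
            None if self.q_true is None else self.q_true[idx],
        )
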