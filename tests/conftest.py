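import numpy as np
import pytest

from arm7ik import IKConfig, default_geometry, generate_joint_trajectory, simulate_recording
from arm7ik.pipeline import initial_pose_from_recording


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interior_q(rng, n=1, margin=0.05):
    """Random joint configurations away from the anatomical boundary."""
    q = rng.uniform(-np.pi / 2 + margin, np.pi / 2 - margin, size=(n, 7))
    return q[0] if n == 1 else q


@pytest.fixture(scope="session")
def short_session(geom):
    """8 s noiseless session with its exact initial pose (shared, read-only)."""
    t, q_true = generate_joint_trajectory(8.0, 0.01, seed=11)
    rec = simulate_recording(t, q_true, geom)
    q0 = initial_pose_from_recording(rec, geom)
    return rec, q_true, q0


@pytest.fixture(scope="session")
def ik_cfg():
    return IKConfig()
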