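import numpy as np
import pytest

from fieldtrack import AnalysisConfig, ArenaGeometry, MotionSpec, Trajectory
from fieldtrack.synthetic import generate_trajectory


@pytest.fixture
def circle_trajectory():
    """Anticlockwise (world-space) circle, radius 100 px, sampled at 2.5 fps."""
    spec = MotionSpec(
        kind="circle", centre_x=160, centre_y=120, radius=100,
        angular_speed=0.5, duration=100, frame_rate=2.5, arena_radius=110,
    )
    return generate_trajectory(spec)


@pytest.fixture
def line_trajectory():
    traj, truth = generate_trajectory(
        MotionSpec(kind="line", centre_x=20, centre_y=120, linear_speed=5,
                   duration=40, frame_rate=2.5)
    )
    return traj, truth


@pytest.fixture
def no_downsample_config():
    return AnalysisConfig(frame_rate=2.5, downsample_factor=1, scale=1.0)


@pytest.fixture
def arena():
    return ArenaGeometry(centre_x=160.0, centre_y=120.0, radius=110.0)


def make_trajectory(x, y, frame_rate=2.5, scale=1.0):
    x = np.asarray(x, dtype=float)
    return Trajectory(np.arange(len(x)), x, y, frame_rate=frame_rate, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
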