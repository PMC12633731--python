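import numpy as np
import pytest

from finstroke.kinematics import LandmarkTrajectory, StrokeCycle
from finstroke.synthdata import GaitSimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cycle():
    """A 1 s cycle with a 0.4 s propulsive phase."""
    return StrokeCycle(0.0, 0.4, 1.0, behaviour="swimming")


@pytest.fixture
def sim_config():
    return GaitSimConfig(seed=7)


def make_trajectory(landmark, t, x=None, y=None, z=None):
    n = len(t)
    zeros = np.zeros(n)
    xyz = np.column_stack([
        zeros if x is None else np.asarray(x, dtype=float),
        zeros if y is None else np.asarray(y, dtype=float),
        zeros if z is None else np.asarray(z, dtype=float),
    ])
    return LandmarkTrajectory(landmark, np.asarray(t, dtype=float), xyz)
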