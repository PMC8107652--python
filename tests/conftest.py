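import numpy as np
import pytest

from mbqmri.signal_models import TimeGrid
from mbqmri.trajectories import (bin_frames, radial_trajectory,
                                 tiny_golden_angle)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_traj():
    """40 golden-angle spokes binned into 5 frames on a 32-grid."""
    flat = radial_trajectory(40, 33, tiny_golden_angle(1), kmax=16.0)
    traj, binning = bin_frames(flat, 8, 5e-3)
    return traj, binning


@pytest.fixture
def small_times(small_traj):
    return TimeGrid(small_traj[1].frame_times)
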