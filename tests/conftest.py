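import numpy as np
import pytest

from gapspec.gap_io import GapTrajectory
from gapspec.state_tracking import ReferenceAxes


@pytest.fixture
def orthogonal_axes() -> ReferenceAxes:
    """Two diabatic labels with orthogonal reference vectors."""
    return ReferenceAxes(labels=("La", "Lb"),
                         vectors=np.array([[1.0, 0.0, 0.0],
                                           [0.0, 1.0, 0.0]]))


@pytest.fixture
def two_state_traj() -> GapTrajectory:
    """Small two-state trajectory with dipoles exactly on the axes."""
    n = 10
    times = np.arange(n) * 5.0
    energies = np.column_stack([np.full(n, 4.4), np.full(n, 4.6)])
    dipoles = np.zeros((n, 2, 3))
    dipoles[:, 0, 0] = 1.0
    dipoles[:, 1, 1] = 1.0
    return GapTrajectory(times=times, energies=energies, dipoles=dipoles)
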