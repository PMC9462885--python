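import numpy as np
import pytest

from hydshell.io import Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trajectory(positions, box, timestep=1.0):
    """Trajectory from (frames, atoms, 3) positions and a cubic box edge."""
    positions = np.asarray(positions, dtype=float)
    boxes = np.tile(np.asarray([box, box, box], dtype=float), (positions.shape[0], 1))
    return Trajectory(timestep=timestep, boxes=boxes, positions=positions % box)


def walker_topology(n, role="OW"):
    """One bare-oxygen molecule per walker."""
    return Topology(
        index=np.arange(n),
        molecule_id=np.arange(n),
        molecule_type=np.array(["WAT"] * n, dtype=object),
        role=np.array([role] * n, dtype=object),
    )
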