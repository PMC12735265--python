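import numpy as np
import pytest

import cryosim as cs


@pytest.fixture(scope="session")
def tissue():
    """Packaged default (liver-like) tissue parameter set."""
    return cs.LIVER


@pytest.fixture(scope="session")
def damage():
    return cs.DamageParams()


@pytest.fixture
def small_grid():
    """Tiny 3-D grid for fast solver unit tests."""
    return cs.SimulationGrid(spacing=2e-3, shape=(8, 8, 8), origin=(0.0, 0.0, -0.016))


@pytest.fixture
def centered_grid():
    """Laterally centered grid able to hold a probe entering at z=0."""
    return cs.SimulationGrid.centered((0.03, 0.03, 0.03), 2e-3)
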