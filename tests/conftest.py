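import numpy as np
import pytest

from pgbm3d import NoiseParams, generalized_anscombe, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cells_small():
    """A 96x96 cells phantom (12-bit count scale)."""
    return make_phantom("cells", size=96, intensity_ceiling=4095.0, seed=5)


@pytest.fixture(scope="session")
def stabilized_cells_small(cells_small):
    """The same phantom on the stabilized scale of a ~100-photon acquisition."""
    return generalized_anscombe(cells_small, NoiseParams(alpha=41.0))
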