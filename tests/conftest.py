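import numpy as np
import pytest

from boldsim import SimulationConfig, generate_network_2d, generate_network_3d


@pytest.fixture(scope="session")
def config():
    """Standard parameter set (3 T, 2%, D = 1 um^2/ms, dt = 0.2 ms ...)."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def small_config():
    """A fast configuration for end-to-end engine runs."""
    return SimulationConfig(n_spins=500, n_voxels=1, radii=(2.0,),
                            total_time=20.0, te_gradient_echo=6.0,
                            te_spin_echo=14.0, seed=7)


@pytest.fixture(scope="session")
def net2d(config):
    return generate_network_2d(config.edge_length_2d, 1.0, 0.02,
                               np.random.default_rng(11))


@pytest.fixture(scope="session")
def net3d(config):
    return generate_network_3d(config.edge_length_3d, 1.0, 0.02,
                               np.random.default_rng(12))
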