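import numpy as np
import pytest

from dnaslide import EnergyLandscape, generate_landscape

#: seed for the rugged reference landscape used across tests (mu = 0.75, N = 100)
RUGGED_SEED = 20110


@pytest.fixture(scope="session")
def flat_landscape() -> EnergyLandscape:
    """100 flat sites: every hop probability is exactly 1/2."""
    return generate_landscape(100, 0.0, 0)


@pytest.fixture(scope="session")
def barrier_landscape() -> EnergyLandscape:
    """Three sites with a 1 k_BT barrier in the middle: U = (0, 1, 0)."""
    return EnergyLandscape(energies=np.array([0.0, 1.0, 0.0]), mu_nominal=0.0, seed=None)


@pytest.fixture(scope="session")
def rugged_landscape() -> EnergyLandscape:
    """One quenched realization at roughness mu = 0.75 k_BT over 100 sites."""
    return generate_landscape(100, 0.75, RUGGED_SEED)
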