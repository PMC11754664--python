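import numpy as np
import pytest

from paibind.docking import OrientationPotential, derive_potential
from paibind.synthetic import SimScenario, gen_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Idealized 10-bp duplex with a 12-residue poly-Ala helix nearby."""
    return gen_toy_complex(SimScenario(
        "toy_complex", {"protein_offset": [10.0, 0.0, 15.0]}, {}, seed=0))


@pytest.fixture(scope="session")
def toy_potential(toy_complex):
    """Inverse-Boltzmann potential trained on the toy complex itself."""
    return derive_potential([toy_complex], pseudocount=0.5)


@pytest.fixture(scope="session")
def zero_potential():
    return OrientationPotential.zeros()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
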