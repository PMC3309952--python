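import numpy as np
import pytest

from fragalign.fixtures import generate_helix, random_walk_decoy


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def helix100():
    return generate_helix(100)


@pytest.fixture(scope="session")
def helix150():
    return generate_helix(150)


@pytest.fixture(scope="session")
def walk100():
    return random_walk_decoy(100, seed=11)
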