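import numpy as np
import pytest

from nanotwin import dep_physics as dp


@pytest.fixture(scope="session")
def medium():
    return dp.default_medium()


@pytest.fixture(scope="session")
def bead_medium():
    return dp.default_bead_medium()


@pytest.fixture(scope="session")
def mito():
    return dp.default_mitochondrion()


@pytest.fixture(scope="session")
def bead():
    return dp.default_ps_bead()


@pytest.fixture(scope="session")
def drive():
    return dp.default_drive()


@pytest.fixture(scope="session")
def tip():
    return dp.default_tip()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
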