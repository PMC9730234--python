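import numpy as np
import pytest

from simet import EnergyLibrary, build_r90_table


@pytest.fixture(scope="session")
def library():
    return EnergyLibrary.default()


@pytest.fixture(scope="session")
def r90_table(library):
    return build_r90_table(library)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
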