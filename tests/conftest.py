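import numpy as np
import pytest

from flownmr import plant_simulator as ps


@pytest.fixture(scope="session")
def model_library():
    return ps.default_model_library()


@pytest.fixture(scope="session")
def nu_map(model_library):
    return {m.name: m.nu for m in model_library}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
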