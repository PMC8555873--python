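import numpy as np
import pytest

from veinmf import KernelSpec, build_bank
from veinmf.synth import generate_phantom, single_bar_config, two_vessel_config


@pytest.fixture(scope="session")
def default_spec():
    return KernelSpec()


@pytest.fixture(scope="session")
def default_bank(default_spec):
    return build_bank(default_spec)


@pytest.fixture(scope="session")
def two_vessel_phantom():
    """Noiseless two parallel vessels with absorption depths 80 and 40."""
    return generate_phantom(two_vessel_config())


@pytest.fixture(scope="session")
def bar_phantoms():
    """Noiseless single straight vessels at 0..165 degrees in 15-degree steps."""
    return {phi: generate_phantom(single_bar_config(phi)) for phi in range(0, 180, 15)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
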