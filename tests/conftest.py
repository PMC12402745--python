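import numpy as np
import pytest

from irai import (
    AcousticMedium,
    TransducerSpec,
    build_array,
)
from irai.array_model import ElementResponse
from irai.grids import VolumeGrid


@pytest.fixture(scope="session")
def spec():
    return TransducerSpec()


@pytest.fixture(scope="session")
def elements(spec):
    return build_array(spec)


@pytest.fixture(scope="session")
def medium():
    return AcousticMedium()


@pytest.fixture(scope="session")
def response():
    return ElementResponse()


@pytest.fixture(scope="session")
def small_spec():
    """8x8 array: wide beam, cheap exhaustive sweeps."""
    return TransducerSpec(n_elements_x=8, n_elements_y=8)


@pytest.fixture(scope="session")
def small_elements(small_spec):
    return build_array(small_spec)


@pytest.fixture(scope="session")
def coarse_volume():
    return VolumeGrid(
        extent=(0.06, 0.06, 0.08), spacing=(0.02, 0.02, 0.02), origin=(-0.03, -0.03, 0.04)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
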