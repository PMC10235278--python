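import numpy as np
import pytest

from nemabench.core import DetectorGeometry
from nemabench.digitizer import DigitizerConfig
from nemabench.materials import DEFAULT_MATERIALS
from nemabench.synthetic_data import PinholeSpec


@pytest.fixture
def geometry():
    return DetectorGeometry()


@pytest.fixture
def pinhole():
    return PinholeSpec(diameter=0.85)


@pytest.fixture
def materials():
    return DEFAULT_MATERIALS


@pytest.fixture
def identity_digitizer():
    return DigitizerConfig().disabled()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
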