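import numpy as np
import pytest

from srmap import geometry


@pytest.fixture(scope="session")
def layout():
    return geometry.build_layout()


@pytest.fixture(scope="session")
def specs(layout):
    return geometry.enumerate_sequences(layout)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
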