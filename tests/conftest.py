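import numpy as np
import pytest

from illusim import pipeline


@pytest.fixture(scope="session")
def small_banks():
    """Reduced banks (4 orientations) for fast solver tests."""
    return pipeline.build_banks(4)


@pytest.fixture(scope="session")
def default_banks():
    return pipeline.build_banks()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
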