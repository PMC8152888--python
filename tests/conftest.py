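import numpy as np
import pytest

from meterlab.patterns import DEFAULT_TEMPLATE, enumerate_unique_patterns


@pytest.fixture(scope="session")
def patterns():
    return enumerate_unique_patterns()


@pytest.fixture(scope="session")
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
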