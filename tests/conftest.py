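import numpy as np
import pytest

from cysreact.encoders import EncoderConfig
from cysreact.synthetic import make_golden_fixtures


@pytest.fixture(scope="session")
def golden():
    """20-protein fixture with hand-verifiable windows and P-dis values."""
    records, sites = make_golden_fixtures()
    return records, sites


@pytest.fixture(scope="session")
def config():
    return EncoderConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
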