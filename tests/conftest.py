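import numpy as np
import pytest

from striatal_stdp import load_default_parameters


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260101)
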