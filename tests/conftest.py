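import numpy as np
import pytest

from burstfield.params import default_parameters


@pytest.fixture(scope="session")
def p():
    """The shipped bursting parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
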