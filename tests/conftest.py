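import numpy as np
import pytest

from ambdimer.constants import DEFAULT_STATE
from ambdimer.landscape import flat_surface, load_default_surface


@pytest.fixture(scope="session")
def state():
    return DEFAULT_STATE


@pytest.fixture(scope="session")
def surface():
    """The calibrated reference surface shipped with the package."""
    return load_default_surface()


@pytest.fixture(scope="session")
def null_surface():
    return flat_surface()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160108)
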