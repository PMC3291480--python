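import numpy as np
import pytest

from jaysim.bird import BirdParams


@pytest.fixture
def params():
    return BirdParams()


@pytest.fixture
def quiet_params():
    """Deterministic bird: no noise, no immediate re-caching, never
    stressed enough to re-cache at recovery."""
    return BirdParams(n=0.0, st=1.0, cr_w=0.0, cr_d=0.0, cr_s=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
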