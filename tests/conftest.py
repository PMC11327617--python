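import numpy as np
import pytest

from gliosurv.discrete_survival import TimeGrid
from gliosurv.preprocessing import VolumeStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    """A five-bin grid with cut points at ~4, 8, 12, 18, 24 months."""
    return TimeGrid((120.0, 240.0, 365.0, 540.0, 730.0))


@pytest.fixture
def small_stack(rng):
    """A 4-channel 16^3 volume stack with an everywhere-positive brain mask."""
    data = rng.normal(1.0, 0.2, size=(4, 16, 16, 16))
    return VolumeStack(data=data, brain_mask=np.ones((16, 16, 16), dtype=bool))
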