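import numpy as np
import pytest


@pytest.fixture
def rec_grid_1hz():
    """A 20,000 s recording grid at the logger's 1 sample/s."""
    return np.arange(0.0, 20001.0, 1.0)


@pytest.fixture
def fine_grid_10hz():
    """A 5,000 s grid at the 0.1 s internal step."""
    return np.arange(0.0, 5000.01, 0.1)
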