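import numpy as np
import pytest

FS = 2000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def t_axis():
    """Standard trial time axis: [-0.5, 0.8) s at 2 kHz."""
    return -0.5 + np.arange(2600) / FS


@pytest.fixture
def fs():
    return FS
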