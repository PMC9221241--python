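import numpy as np
import pytest

from feccnet.architecture import NetworkConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mini_net_config():
    """Smallest sensible network: depth 2, 32x32 input, float64 for exactness."""
    return NetworkConfig(
        input_size=32,
        depth=2,
        channel_schedule=(8, 16),
        aspp_rates=(1, 2),
        aspp_channels=8,
        enhanced_schedule=(8, 16),
        enhanced_stack=1,
        dtype="float64",
    )
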