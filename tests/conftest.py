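import numpy as np
import pytest

from omicsdiff import DenoiserConfig, make_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def schedule10():
    return make_schedule("linear", T=10, beta_start=0.01, beta_end=0.2)


@pytest.fixture
def schedule2():
    return make_schedule("linear", T=2, beta_start=0.1, beta_end=0.2)


@pytest.fixture
def tiny_config():
    """Smallest U-Net that still exercises every branch (16x16, depth 2)."""
    return DenoiserConfig(
        image_size=16, cond_dim=8, base_channels=8, depth=2,
        channel_mults=(1, 2), time_embed_dim=16, blocks_per_stage=1,
    )
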