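import numpy as np
import pytest

from synthreg.fields import sample_lowres_gaussian, upsample_field


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def smooth_field(shape, r, sd, seed=42):
    """A fixed smooth random vector field at full resolution."""
    gen = np.random.default_rng(seed)
    low = sample_lowres_gaussian(shape, r, sd, channels=len(shape), rng=gen)
    return upsample_field(low, shape)


@pytest.fixture
def small_smooth_svf():
    """Small-amplitude smooth velocity field on a 32^2 grid."""
    return smooth_field((32, 32), "1:8", 0.4)
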