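import numpy as np
import pytest

from pamgan.io_volumes import Modality, PamVolume, ValueScale


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """Random float volume, shape (4, 6, 5), unit scale."""
    data = rng.random((4, 6, 5))
    return PamVolume(data=data, dx=5.0, dy=5.0, dz=10.0,
                     modality=Modality.AR, value_scale=ValueScale.FLOAT_UNIT)


@pytest.fixture
def uint8_volume(rng):
    data = rng.integers(0, 256, size=(3, 8, 7)).astype(np.uint8)
    return PamVolume(data=data, dx=5.0, dy=5.0, dz=10.0,
                     modality=Modality.OR, value_scale=ValueScale.UINT8)
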