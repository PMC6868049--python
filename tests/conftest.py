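import numpy as np
import pytest

from rfradiomics import AcquisitionGeometry, WindowSpec


@pytest.fixture(scope="session")
def geometry():
    """Full-size default acquisition geometry (20 MHz / 3 MHz, 2048 x 128)."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A small frame for fast plumbing tests."""
    return AcquisitionGeometry(n_scanlines=32, samples_per_line=512)


@pytest.fixture(scope="session")
def small_window():
    return WindowSpec(axial_len=64, lateral_len=4, axial_step=32, lateral_step=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_quantized(rng, shape=(8, 8), levels=4):
    """A random already-quantised image with values in [1, levels]."""
    return rng.integers(1, levels + 1, size=shape)
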