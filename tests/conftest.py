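import numpy as np
import pytest

from spillsmooth.model import IntensityImage, LabelMask
from spillsmooth.simulate import ChannelSpec, SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small dense simulated field at 1 μm resolution (noisy channel)."""
    cfg = SimulationConfig(
        field_um=(60.0, 60.0),
        super_res_px_per_um=1,
        seed=7,
        channels=[ChannelSpec("ch0")],
    )
    return simulate_dataset(cfg)


@pytest.fixture
def two_cell_mask():
    """Two touching 4×4 cells side by side on a 10×12 canvas."""
    labels = np.zeros((10, 12), dtype=np.int64)
    labels[3:7, 2:6] = 1
    labels[3:7, 6:10] = 2
    return LabelMask(labels)


@pytest.fixture
def constant_image():
    def make(shape, value=5.0):
        return IntensityImage(np.full(shape, float(value)))

    return make
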