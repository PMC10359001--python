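import numpy as np
import pytest

from canedisc.design import enumerate_pairs, enumerate_samples, step2_design
from canedisc.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def step2():
    """Dual-block study subset: design, samples and classified pairs."""
    design = step2_design()
    samples = enumerate_samples(design)
    return design, samples, enumerate_pairs(samples)


@pytest.fixture(scope="session")
def small_bundle():
    """Compact synthetic bundle (small images) shared by slow-ish tests."""
    cfg = SyntheticConfig(image_size=(80, 80), leaf_axes=(22.0, 32.0), seed=5)
    return generate_dataset(cfg)


@pytest.fixture()
def disk_image():
    """Green disk (radius 20) on a white background, with its true mask."""
    h = w = 64
    yy, xx = np.mgrid[0:h, 0:w]
    mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
    img = np.full((h, w, 3), 250, dtype=np.uint8)
    img[mask] = (40, 150, 60)
    return img, mask
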