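import numpy as np
import pytest

from dolphinseg.samples import ImageSample
from dolphinseg.synthetic import LesionSimConfig, generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lesion_samples():
    """A small default-condition synthetic lesion set shared across tests."""
    return generate_samples(12, LesionSimConfig(), seed=11)


@pytest.fixture
def checker_sample():
    """A trivially separable image: dark foreground quadrant on bright ground."""
    pixels = np.full((16, 16), 0.8)
    mask = np.zeros((16, 16), dtype=np.int64)
    mask[:8, :8] = 1
    pixels[:8, :8] = 0.2
    return ImageSample(pixels, mask, id="checker")


def random_mask_pair(rng, shape=(12, 13), p=0.4):
    pred = (rng.random(shape) < p).astype(np.int64)
    truth = (rng.random(shape) < p).astype(np.int64)
    return pred, truth
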