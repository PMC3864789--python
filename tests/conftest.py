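import numpy as np
import pytest

from neovessel.preprocess import PreprocessConfig, preprocess_image
from neovessel.synth import SynthConfig, make_image


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_positive():
    """One positive synthetic fundus image with its ground truth."""
    image, mask, label = make_image(SynthConfig(seed=3, tuft_density=0.8))
    assert label == 1
    return image, mask


@pytest.fixture(scope="session")
def preprocessed(synth_positive):
    """Preprocessing result of the session's positive image (small-image
    settings, matching the synthetic study)."""
    image, _ = synth_positive
    return preprocess_image(image, PreprocessConfig.for_small_images())
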