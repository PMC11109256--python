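import numpy as np
import pytest

from dlanet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 12-image synthetic dataset shared by IO-level tests."""
    out = tmp_path_factory.mktemp("smallds")
    config = SyntheticConfig(n_images=12, image_height=96, image_width=96, seed=7)
    manifest = generate_dataset(config, out)
    return config, out, manifest


def rect_mask(height=128, width=128, rows=(10, 110), left_cols=(20, 50), right_cols=(78, 108)):
    """Two-rectangle stand-in lung mask (image-left block = anatomical right lung)."""
    mask = np.zeros((height, width), dtype=bool)
    mask[rows[0] : rows[1] + 1, left_cols[0] : left_cols[1] + 1] = True
    mask[rows[0] : rows[1] + 1, right_cols[0] : right_cols[1] + 1] = True
    return mask
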