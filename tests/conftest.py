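import numpy as np
import pytest

from irisseg import ModelConfig, IrisSegNet
from irisseg.synthetic import generate_dataset
from irisseg.data import discover_pairs, load_image, load_mask


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def synth_dir(tmp_path_factory):
    """A small deterministic synthetic dataset (shared across tests)."""
    out = tmp_path_factory.mktemp("synth")
    generate_dataset(12, 0.5, out, seed=0)
    return out


@pytest.fixture(scope="session")
def overfit_set(tmp_path_factory):
    """The 16-image training fixture at the desk-scale input size."""
    out = tmp_path_factory.mktemp("overfit")
    generate_dataset(16, 0.5, out, seed=0)
    pairs = discover_pairs(out)
    images = np.stack([load_image(p.image_path, 64) for p in pairs])
    masks = np.stack([load_mask(p.mask_path, 64) for p in pairs])
    return images, masks


@pytest.fixture
def tiny_model():
    """A narrow 64-px model for fast structural tests."""
    return IrisSegNet(ModelConfig.scaled(4, 64, random_seed=1))
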