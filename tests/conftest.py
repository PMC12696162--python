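import numpy as np
import pytest

from leafdet.modules import seed_init


@pytest.fixture(autouse=True)
def _seeded_init():
    """Every test builds layers from the same deterministic init stream."""
    seed_init(1234)
    np.random.seed(1234)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small rendered dataset shared across IO/training smoke tests."""
    from leafdet.synthdata import SceneConfig, generate_dataset

    root = tmp_path_factory.mktemp("tinyds")
    cfg = SceneConfig(n_images=12, image_size=96, lesions_per_image=(1, 2),
                      seed=5)
    manifest = generate_dataset(cfg, root)
    return root, cfg, manifest
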