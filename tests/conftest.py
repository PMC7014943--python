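import numpy as np
import pytest

import voxseg as vs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def brats_phantom():
    """One noiseless five-class phantom on a small grid."""
    cfg = vs.PhantomConfig(shape=(8, 40, 40), n_modalities=4, noise_sigma=0.0, seed=3)
    return vs.make_phantom(cfg), cfg


@pytest.fixture(scope="session")
def noisy_dataset():
    """Four noisy phantoms, the desk-scale training conditions."""
    cfg = vs.PhantomConfig(shape=(8, 40, 40), n_modalities=4, seed=7)
    return vs.make_dataset(4, cfg, 7), cfg


@pytest.fixture(scope="session")
def tiny_model():
    """A small but structurally complete network for shape/gradient tests."""
    cfg = vs.ModelConfig(
        n_modalities=4, n_classes=5, block_channels=(8, 16, 32, 64), refine_channels=16, seed=1
    )
    model, desc = vs.build_model(cfg)
    return model, desc, cfg
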