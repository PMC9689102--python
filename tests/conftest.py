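import numpy as np
import pytest
from hypothesis import settings

import cystoseg as cs
from cystoseg.scheme import CANCER

# property tests must be reproducible across runs
settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 16 x 16 RGB frame with strictly interior values."""
    return 0.05 + 0.9 * rng.random((16, 16, 3))


@pytest.fixture
def cancer_scene():
    """One 64 x 64 scene with a single cancer lesion and its exact mask."""
    spec = cs.SceneSpec(image_size=64, n_lesions=1, class_pool=(CANCER,),
                        lesion_area_range=(150, 600), seed=42)
    return cs.make_scene(spec)


@pytest.fixture(scope="session")
def overfit_model_and_pair():
    """A tiny net overfitted on one scene; shared across tests."""
    spec = cs.SceneSpec(image_size=64, n_lesions=1, class_pool=(CANCER,),
                        lesion_area_range=(200, 600), seed=7)
    img, mask = cs.make_scene(spec)
    std = cs.standardize(img)
    net = cs.reference_model(seed=7, base_channels=8)
    alpha = cs.class_alphas([mask])
    cfg = cs.TrainConfig(epochs=50, batch_size=1, learning_rate=3e-3,
                         gamma=2.0, alpha=alpha, seed=7)
    history = cs.train(net, [(std, mask)], cfg)
    return net, std, mask, history
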