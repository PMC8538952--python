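import numpy as np
import pytest

from lodgeseg.raster_io import LabelMask, Raster, TilePair
from lodgeseg.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def rgb_raster(rng):
    return Raster(rng.random((16, 24, 3)), ("R", "G", "B"))


@pytest.fixture
def small_pair(rng):
    """8×8 RGB tile with a random 3-class mask."""
    return TilePair(
        Raster(rng.random((8, 8, 3)), ("R", "G", "B")),
        LabelMask(rng.integers(0, 3, (8, 8))),
    )


@pytest.fixture(scope="session")
def default_scene():
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture(scope="session")
def trained_small_model():
    """A small RGB+DSM Mobile U-Net trained on easy synthetic scenes.

    Session-scoped: shared by the prediction, Grad-CAM and checkpoint tests.
    """
    from lodgeseg.experiments import train_demo_model

    model, cfg = train_demo_model(seed=0, epochs=25)
    return model, cfg
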