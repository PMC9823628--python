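import numpy as np
import pytest

from pearnet.arch import ModelConfig, build_model
from pearnet.data_io import BoundingBox
from pearnet.synthgen import SceneSpec, make_fixture_set


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Small-input configuration used for fast structural tests."""
    return ModelConfig(variant="baseline", input_size=64, width_multiple=0.25)


@pytest.fixture(scope="session")
def tiny_model(tiny_cfg):
    return build_model(tiny_cfg, seed=0)


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """Small on-disk synthetic dataset in the images/ + labels/ layout."""
    root = tmp_path_factory.mktemp("scenes")
    spec = SceneSpec(image_size=96, n_pears=4, occlusion_fraction=0.2)
    index = make_fixture_set(8, spec, seed=11, out_dir=root)
    return root, index


def box(cx, cy, w, h, cls=0, conf=None, tags=None):
    return BoundingBox(cls, cx, cy, w, h, confidence=conf, tags=tags)


@pytest.fixture
def make_box():
    return box
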