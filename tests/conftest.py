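import numpy as np
import pytest

from pestdet.network import ModelSpec, build_model
from pestdet.scenes import SceneConfig, render_scene
from pestdet.yolo_io import LabeledImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small working size for fast forward passes; default widths."""
    return ModelSpec(input_size=64)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return build_model(tiny_spec, seed=0)


def make_scenes(n, size=64, seed=11, frac=(0.45, 0.7), clutter=0.0,
                objects=(1, 1)):
    cfg = SceneConfig(image_size=size, objects_per_image=objects,
                      object_size_fraction=frac, clutter_level=clutter,
                      seed=seed)
    out = []
    for i in range(n):
        s = render_scene(cfg, np.random.default_rng([seed, i]),
                         primary_class=i % 5)
        out.append(LabeledImage(s.pixels, s.boxes, f"img{i}"))
    return out


@pytest.fixture(scope="session")
def small_scene_batch():
    return make_scenes(6)
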