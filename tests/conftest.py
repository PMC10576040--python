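import numpy as np
import pytest

from mountdet import layers
from mountdet.data_io_aug import LabeledImage, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_scene_cfg():
    return SceneConfig(canvas=(128, 128), n_animals=(2, 4),
                       mounting_pairs=(1, 1), scale_range=(0.6, 1.0),
                       night_prob=0.25)


@pytest.fixture
def tiny_samples(tiny_scene_cfg):
    r = np.random.default_rng(7)
    samples = []
    for v in range(4):
        for _ in range(2):
            s = generate_scene(tiny_scene_cfg, r)
            s.source_video = f"vid{v:02d}"
            samples.append(s)
    return samples


@pytest.fixture
def seeded_weights():
    layers.seed_all(0)
    yield
    layers.seed_all(0)


def random_labeled_image(rng, size=64, n_boxes=2) -> LabeledImage:
    img = rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8)
    boxes = []
    for _ in range(n_boxes):
        w, h = rng.uniform(0.1, 0.4, 2)
        cx = rng.uniform(w / 2, 1 - w / 2)
        cy = rng.uniform(h / 2, 1 - h / 2)
        boxes.append([0, cx, cy, w, h])
    return LabeledImage(img, np.array(boxes), source_video="v0")
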