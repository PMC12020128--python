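import numpy as np
import pytest

from cdpd.mtdam import TrainConfig, make_dual_branch_model, train
from cdpd.synthetic_scenes import SceneSpec, generate_scene

TOY_IMAGE_SIZE = 48


@pytest.fixture(scope="session")
def single_object_spec():
    return SceneSpec(image_height=TOY_IMAGE_SIZE, image_width=TOY_IMAGE_SIZE,
                     num_classes=3, objects_per_image=(1, 1),
                     object_scale=(0.18, 0.3), seed=3)


@pytest.fixture(scope="session")
def toy_scenes(single_object_spec):
    """Eight fixed single-object scenes used by the training tests."""
    return [generate_scene(single_object_spec, i) for i in range(8)]


@pytest.fixture(scope="session")
def multi_object_scenes():
    spec = SceneSpec(image_height=TOY_IMAGE_SIZE, image_width=TOY_IMAGE_SIZE,
                     num_classes=3, objects_per_image=(1, 2),
                     object_scale=(0.15, 0.28), seed=11)
    return [generate_scene(spec, i) for i in range(24)]


@pytest.fixture(scope="session")
def trained_state(multi_object_scenes):
    """Parameters of a briefly trained dual-branch model (trained once)."""
    cfg = TrainConfig(epochs=40, image_size=TOY_IMAGE_SIZE, batch_size=8,
                      lr_init=0.04, lr_final=0.01, dag_lr=0.02,
                      schedule="cosine", seed=0)
    model = make_dual_branch_model(3, image_size=TOY_IMAGE_SIZE, seed=0)
    train(model, multi_object_scenes, cfg)
    return model.state_dict()


@pytest.fixture()
def trained_model(trained_state):
    """A fresh model loaded from the shared trained parameters; safe to
    mutate (adaptation tests update weights in place)."""
    model = make_dual_branch_model(3, image_size=TOY_IMAGE_SIZE, seed=0)
    model.load_state_dict(trained_state)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
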