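import numpy as np
import pytest

from bsdnet.model import ModelConfig, build_model
from bsdnet.synthetic import SceneSpec, generate_dataset
from bsdnet.train import TrainConfig, fit

SMOKE_SPEC = SceneSpec(n_categories=3, n_images=8, image_size=(64, 64),
                       object_scale=(12, 28), imbalance_exponent=1.0,
                       objects_per_image=(2, 3), seed=7)


@pytest.fixture(scope="session")
def tiny_dataset():
    dataset, ledger = generate_dataset(SMOKE_SPEC)
    return dataset, ledger


@pytest.fixture(scope="session")
def overfit_run(tiny_dataset):
    """200 training iterations of the reduced-width model on 8 scenes;
    shared by the optimisation-sanity and detection-quality checks."""
    dataset, _ = tiny_dataset
    cfg = ModelConfig(n_categories=3, scale="tiny", input_size=(64, 64))
    model = build_model(cfg, seed=0)
    model, history = fit(model, dataset, TrainConfig(
        epochs=200, batch_size=8, augment=False, mosaic_off_last=0, seed=0))
    return model, history, dataset
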