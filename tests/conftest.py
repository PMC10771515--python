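import numpy as np
import pytest

from twinfuse import extractors, synthetic


@pytest.fixture(scope="session")
def mammo_batch():
    """120 synthetic mammography-like images, two separable classes."""
    spec = synthetic.SyntheticImageSpec(
        n_per_class=60, classes=("N", "M"), size=(32, 32), channels=1, seed=0)
    return synthetic.gen_mammo_like(spec)


@pytest.fixture(scope="session")
def trained_model(mammo_batch):
    """Mini extractor trained to separability on the mammography batch."""
    spec = extractors.mini_spec(channels=1, n_classes=2)
    model = extractors.build_extractor(spec, seed=0)
    cfg = extractors.TrainConfig(learning_rate=1e-3, epochs=12, seed=0)
    model, history = extractors.train(model, mammo_batch, cfg=cfg)
    return model, history


@pytest.fixture(scope="session")
def informative_matrix():
    """n=200, dim=10 feature matrix with informative columns {2, 5, 7}."""
    fm, y, mask = synthetic.gen_feature_matrix(
        n=200, dim=10, informative=[2, 5, 7], effect=3.0, seed=0)
    return fm, np.asarray(y), mask


@pytest.fixture(scope="session")
def table4_records():
    return synthetic.table4_fixture()
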