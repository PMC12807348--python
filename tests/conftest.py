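import numpy as np
import pytest

from msdquant import FixtureConfig, make_dataset, make_model, train_model


@pytest.fixture(scope="session")
def dataset():
    return make_dataset(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model(dataset):
    model = make_model("mini", seed=1)
    train_model(model, dataset, epochs=25, seed=1)
    return model


@pytest.fixture(scope="session")
def calib_batch(dataset):
    return dataset.train_images[:32][:, None, :, :]
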