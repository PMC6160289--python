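import numpy as np
import pytest

import canopycenter as cc


@pytest.fixture(scope="session")
def default_fixture():
    """One default-parameter synthetic canopy frame with ground truth."""
    return cc.generate_canopy_image(cc.FixtureParams(seed=1))


@pytest.fixture(scope="session")
def trained_model():
    """Pixel classifier trained once on three default-parameter fixtures."""
    fixtures, _ = cc.generate_dataset(3, ranges={}, seed=42)
    return cc.train_from_fixtures(fixtures)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_mask(rng, shape=(20, 20), p=0.5):
    return cc.BinaryMask((rng.random(shape) < p).astype(np.uint8))
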