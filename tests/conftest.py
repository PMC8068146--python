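import dataclasses

import numpy as np
import pytest

from spinet.config import TrainConfig
from spinet.model import toy_model_config
from spinet.synthetic import SceneParams, generate_scene
from spinet.training import fit


def make_scenes(n, size=64, seed0=1000, **overrides):
    base = SceneParams.for_size(size, size, **overrides)
    return [generate_scene(dataclasses.replace(base, seed=seed0 + i)) for i in range(n)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_train_config():
    return TrainConfig(model=toy_model_config(), epochs=25, batch_size=4, seed=0)


@pytest.fixture(scope="session")
def trained_toy(toy_train_config):
    """Toy model trained 200 iterations (25 epochs × 8 batches) on 32 synthetic
    64×64 scenes, with 8 held-out validation scenes.  Shared across tests that
    need a converged model."""
    train_pairs = make_scenes(32, seed0=1000)
    val_pairs = make_scenes(8, seed0=2000)
    result = fit(train_pairs, val_pairs, toy_train_config)
    return result, val_pairs
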