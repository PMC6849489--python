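"""Shared fixtures: bundled models, scan datasets and pre-trained networks.

Training fixtures are session-scoped — several tests probe the same
surrogate surface and training is the expensive step.
"""

import numpy as np
import pytest

from photodyn.io import Dataset
from photodyn.models import (AvoidedCrossingModel, ConicalIntersectionModel,
                             SequentialDecayModel)
from photodyn.nn import Hyperparams, TrainingSet, train


def diatomic_scan(model, r_values):
    return [model.make_geometry(np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]))
            for r in r_values]


@pytest.fixture()
def ac_model():
    return AvoidedCrossingModel()


@pytest.fixture()
def ci_model():
    return ConicalIntersectionModel()


@pytest.fixture()
def decay_model():
    return SequentialDecayModel()


@pytest.fixture(scope="session")
def ac_dataset():
    model = AvoidedCrossingModel()
    return Dataset.from_provider(model, diatomic_scan(model, np.linspace(1.6, 4.6, 60)))


@pytest.fixture(scope="session")
def ac_nn(ac_dataset):
    ts = TrainingSet.random_split(ac_dataset, 0.15, seed=0)
    return train(ts, Hyperparams(epochs=2000), seed=1)


def _ci_geometries(model, n, spread, seed):
    rng = np.random.default_rng(seed)
    base = model.meci_geometry().coords
    return [model.make_geometry(base + rng.normal(0, spread, base.shape))
            for _ in range(n)]


@pytest.fixture(scope="session")
def ci_training_geometries():
    return _ci_geometries(ConicalIntersectionModel(), 220, 0.25, seed=3)


@pytest.fixture(scope="session")
def ci_nn(ci_training_geometries):
    model = ConicalIntersectionModel()
    ds = Dataset.from_provider(model, ci_training_geometries)
    ts = TrainingSet.random_split(ds, 0.15, seed=0)
    return train(ts, Hyperparams(hidden=(64, 64), epochs=4000, eval_every=50,
                                 patience=20, learning_rate=3e-3), seed=2)


@pytest.fixture(scope="session")
def decay_nn():
    from photodyn.experiments import train_sequential_decay_nn

    return train_sequential_decay_nn(seed=0)
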