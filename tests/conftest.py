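"""Shared fixtures: small synthetic datasets and a tiny trained model.

Everything is generated programmatically at collection time; no fixture
files on disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from stereoflag import (
    ModelConfig,
    SyntheticSpec,
    build_reaction_graph,
    generate,
    train,
)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic reactions, low noise, a few planted flips."""
    spec = SyntheticSpec(
        n_reactions=60, noise_sd=2.0, flip_fraction=0.05, seed=7
    )
    ds, truth = generate(spec)
    return ds, truth


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    ds, _ = small_dataset
    return [build_reaction_graph(r) for r in ds]


@pytest.fixture(scope="session")
def tiny_model(small_graphs):
    """A briefly trained model for architecture/contract tests."""
    cfg = ModelConfig(seed=5, max_epochs=5)
    return train(small_graphs[:40], small_graphs[40:50], cfg)


class ConstantModel:
    """Stand-in regressor that predicts a fixed value for every graph."""

    def __init__(self, value: float):
        self.value = value
        self.training_log = []

    def predict(self, graphs):
        return np.full(len(graphs), self.value)


@pytest.fixture
def constant_trainer():
    def make(value: float):
        def trainer(train_graphs, val_graphs, cfg):
            return ConstantModel(value)

        return trainer

    return make
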