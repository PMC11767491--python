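"""Architecture contract, training schedule, and determinism of the GNN."""

import numpy as np
import pytest

from stereoflag.featurization import ReactionGraph, build_reaction_graph
from stereoflag.gnn import (
    EarlyStopping,
    ModelConfig,
    PlateauLR,
    TrainedModel,
    forward,
    train,
)


def _single_node_graph(target=50.0):
    feats = np.zeros((1, 24))
    feats[0, [1, 8, 15, 17, 19, 23]] = 1.0  # a carbon-like one-hot row
    return ReactionGraph(
        node_features=feats, adjacency=[],
        component_of=np.array(["ligand"]), target=target, reaction_id=0,
    )


def _permuted(g: ReactionGraph, rng) -> ReactionGraph:
    perm = rng.permutation(g.n_nodes)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(g.n_nodes)
    return ReactionGraph(
        node_features=g.node_features[perm],
        adjacency=[(min(inv[i], inv[j]), max(inv[i], inv[j])) for i, j in g.adjacency],
        component_of=g.component_of[perm],
        target=g.target,
        reaction_id=g.reaction_id,
    )


class TestConfig:
    def test_pooled_must_be_twice_hidden(self):
        with pytest.raises(ValueError, match="pooled_dim"):
            ModelConfig(hidden_dim=64, pooled_dim=100)

    def test_defaults_match_training_recipe(self):
        cfg = ModelConfig()
        assert (cfg.batch_size, cfg.lr_init, cfg.lr_factor) == (40, 0.01, 0.7)
        assert (cfg.lr_patience_epochs, cfg.early_stop_patience_epochs) == (5, 30)
        assert cfg.lr_min == 1e-8


class TestForward:
    def test_scalar_finite_output(self, tiny_model, small_graphs):
        for g in small_graphs[:5]:
            y = forward(g, tiny_model)
            assert isinstance(y, float) and np.isfinite(y)

    def test_pooled_vector_width_128(self, tiny_model, small_graphs):
        assert tiny_model.pooled_vector(small_graphs[0]).shape == (128,)

    def test_single_node_mean_equals_max_pool(self, tiny_model):
        pooled = tiny_model.pooled_vector(_single_node_graph())
        assert np.allclose(pooled[:64], pooled[64:])

    def test_node_permutation_invariance(self, tiny_model, small_graphs):
        rng = np.random.default_rng(0)
        for g in small_graphs[:5]:
            y0 = forward(g, tiny_model)
            for _ in range(3):
                assert forward(_permuted(g, rng), tiny_model) == pytest.approx(
                    y0, abs=1e-5
                )


class TestSchedules:
    def test_plateau_decays_after_patience(self):
        sched = PlateauLR(0.01, 0.7, patience=5, lr_min=1e-8)
        sched.step(1.0)  # improvement (first value)
        for _ in range(4):
            assert sched.step(1.0) == 0.01  # 4 flat epochs: no decay yet
        assert sched.step(1.0) == pytest.approx(0.007)  # 5th flat epoch

    def test_plateau_counter_resets_on_improvement(self):
        sched = PlateauLR(0.01, 0.7, patience=5, lr_min=1e-8)
        sched.step(1.0)
        for _ in range(4):
            sched.step(1.0)
        sched.step(0.5)  # strict improvement resets the counter
        for _ in range(4):
            assert sched.step(0.5) == 0.01
        assert sched.step(0.5) == pytest.approx(0.007)

    def test_lr_never_below_floor(self):
        sched = PlateauLR(0.01, 0.7, patience=1, lr_min=1e-8)
        sched.step(1.0)
        for _ in range(200):
            lr = sched.step(1.0)
            assert lr >= 1e-8
        assert lr == 1e-8

    def test_early_stop_after_30_flat_epochs(self):
        stop = EarlyStopping(patience=30)
        assert not stop.step(1.0)
        flags = [stop.step(1.0) for _ in range(30)]
        assert flags[:-1] == [False] * 29 and flags[-1] is True

    def test_equal_loss_is_not_improvement(self):
        stop = EarlyStopping(patience=2)
        stop.step(1.0)
        assert not stop.step(1.0)
        assert stop.step(1.0)


class TestTraining:
    def test_deterministic_log_for_fixed_seed(self, small_graphs):
        cfg = ModelConfig(seed=42, max_epochs=8)
        m1 = train(small_graphs[:30], small_graphs[30:40], cfg)
        m2 = train(small_graphs[:30], small_graphs[30:40], cfg)
        assert m1.training_log == m2.training_log  # bitwise identical
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_lr_sequence_non_increasing_with_floor(self, small_graphs):
        cfg = ModelConfig(seed=1, max_epochs=40)
        m = train(small_graphs[:30], small_graphs[30:40], cfg)
        lrs = [row["lr"] for row in m.training_log]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))
        assert all(lr >= cfg.lr_min for lr in lrs)

    def test_early_stopping_terminates_training(self, small_graphs):
        cfg = ModelConfig(seed=2, max_epochs=500)
        m = train(small_graphs[:30], small_graphs[30:40], cfg)
        n_epochs = len(m.training_log)
        assert n_epochs < 500
        # halt comes exactly 30 epochs after the last validation improvement
        val = [row["val_rmse"] for row in m.training_log]
        best_epoch = int(np.argmin(val)) + 1
        assert n_epochs == best_epoch + 30
        assert m.best_epoch == best_epoch

    def test_memorizes_tiny_training_set(self, small_graphs):
        """Capacity check: 10 graphs with val=train reach <1 %top RMSE."""
        cfg = ModelConfig(seed=3, max_epochs=600, batch_size=10)
        subset = small_graphs[:10]
        m = train(subset, subset, cfg)
        assert min(r["train_rmse"] for r in m.training_log) < 1.0

    def test_best_epoch_weights_returned(self, small_graphs):
        cfg = ModelConfig(seed=4, max_epochs=60)
        m = train(small_graphs[:30], small_graphs[30:40], cfg)
        val = np.array([r["val_rmse"] for r in m.training_log])
        preds = m.predict(small_graphs[30:40])
        labels = np.array([g.target for g in small_graphs[30:40]])
        rmse = float(np.sqrt(np.mean((preds - labels) ** 2)))
        assert rmse == pytest.approx(val.min(), abs=1e-9)

    def test_empty_sets_rejected(self, small_graphs):
        with pytest.raises(ValueError):
            train([], small_graphs[:5], ModelConfig())

    def test_checkpoint_roundtrip(self, tiny_model, small_graphs, tmp_path):
        path = tmp_path / "model.json"
        tiny_model.save(path)
        back = TrainedModel.load(path)
        assert np.array_equal(
            back.predict(small_graphs[:5]), tiny_model.predict(small_graphs[:5])
        )
        assert back.config == tiny_model.config
        assert back.schema == tiny_model.schema
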