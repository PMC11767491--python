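"""Graph-convolutional %top regressor and its training loop.

Architecture (fixed by design, widths configurable only in lockstep):

    X (n×24) --GCNconv+leakyReLU--> (n×64) --GCNconv+leakyReLU--> (n×64)
      --[mean-pool ‖ max-pool over nodes]--> (1×128)
      --dense+leakyReLU--> (1×64) --dense--> scalar %top prediction

The graph convolution is the symmetric-normalized neighbourhood average
with self-loops, Â = D^{-1/2}(A+I)D^{-1/2}, applied as Â·H·W + b.

Training: Adam on a per-batch RMSE loss, batches of 40 graphs; after each
epoch the validation RMSE drives (a) a reduce-on-plateau learning-rate
schedule (×0.7 after 5 epochs without strict improvement, floored at
1e-8) and (b) early stopping after 30 epochs without improvement.  The
weights returned are those of the best-validation epoch.  Everything is
plain float64 NumPy, so training is bitwise reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .featurization import NodeFeatureSchema, ReactionGraph, DEFAULT_SCHEMA

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "TrainingError",
    "PlateauLR",
    "EarlyStopping",
    "train",
    "forward",
]


class TrainingError(RuntimeError):
    """Non-finite loss or other unrecoverable training failure."""


@dataclass(frozen=True)
class ModelConfig:
    """All architecture and schedule hyperparameters in one place."""

    in_dim: int = 24
    hidden_dim: int = 64
    pooled_dim: int = 128
    dense_dim: int = 64
    out_dim: int = 1
    batch_size: int = 40
    lr_init: float = 0.01
    lr_factor: float = 0.7
    lr_patience_epochs: int = 5
    lr_min: float = 1e-8
    early_stop_patience_epochs: int = 30
    max_epochs: int = 1000
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pooled_dim != 2 * self.hidden_dim:
            raise ValueError("pooled_dim must equal 2 * hidden_dim")
        if self.lr_patience_epochs <= 0 or self.early_stop_patience_epochs <= 0:
            raise ValueError("patience values must be positive")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if self.max_epochs <= 0:
            raise ValueError("max_epochs must be positive")


class PlateauLR:
    """Reduce-on-plateau schedule: lr *= factor after `patience` epochs
    without strict improvement of the monitored loss; never below lr_min."""

    def __init__(self, lr_init: float, factor: float, patience: int, lr_min: float):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.lr_min = lr_min
        self.best = np.inf
        self._bad = 0

    def step(self, loss: float) -> float:
        if loss < self.best:
            self.best = loss
            self._bad = 0
        else:
            self._bad += 1
            if self._bad >= self.patience:
                self.lr = max(self.lr * self.factor, self.lr_min)
                self._bad = 0
        return self.lr


class EarlyStopping:
    """Stop after `patience` epochs without strict improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self._bad = 0

    def step(self, loss: float) -> bool:
        if loss < self.best:
            self.best = loss
            self._bad = 0
            return False
        self._bad += 1
        return self._bad >= self.patience


# --------------------------------------------------------------------------
# graph pre-processing


def _norm_adjacency(g: ReactionGraph) -> sp.csr_matrix:
    n = g.n_nodes
    if g.adjacency:
        ij = np.asarray(g.adjacency, dtype=np.int64)
        rows = np.concatenate([ij[:, 0], ij[:, 1], np.arange(n)])
        cols = np.concatenate([ij[:, 1], ij[:, 0], np.arange(n)])
    else:
        rows = cols = np.arange(n)
    a = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    dinv = 1.0 / np.sqrt(np.asarray(a.sum(axis=1)).ravel())
    d = sp.diags(dinv)
    return (d @ a @ d).tocsr()


@dataclass
class _Prep:
    """Per-graph cache: normalized adjacency and pre-propagated features."""

    a_hat: sp.csr_matrix
    m0: np.ndarray  # Â @ X, shape (n, in_dim)
    n: int
    target: float
    reaction_id: int


def prepare_graphs(graphs: Sequence[ReactionGraph]) -> list[_Prep]:
    out = []
    for g in graphs:
        a = _norm_adjacency(g)
        out.append(
            _Prep(a, a @ g.node_features, g.n_nodes, g.target, g.reaction_id)
        )
    return out


class _Batch:
    """Block-diagonal assembly of several prepared graphs.

    The combined normalized adjacency is built by direct CSR
    concatenation (shifting column indices and indptr), which is much
    cheaper than a generic block-diagonal construction.
    """

    def __init__(self, preps: Sequence[_Prep]):
        sizes = np.array([p.n for p in preps])
        stops = np.cumsum(sizes)
        starts = stops - sizes
        n = int(stops[-1])
        data = np.concatenate([p.a_hat.data for p in preps])
        indices = np.concatenate(
            [p.a_hat.indices + off for p, off in zip(preps, starts)]
        )
        indptr = np.empty(n + 1, dtype=np.int64)
        indptr[0] = 0
        pos = 0
        nnz = 0
        for p in preps:
            indptr[pos + 1 : pos + p.n + 1] = p.a_hat.indptr[1:] + nnz
            pos += p.n
            nnz += p.a_hat.indptr[-1]
        self.a = sp.csr_matrix((data, indices, indptr), shape=(n, n))
        self.m0 = np.vstack([p.m0 for p in preps])
        self.slices = [slice(int(a), int(b)) for a, b in zip(starts, stops)]
        self.y = np.array([p.target for p in preps])


# --------------------------------------------------------------------------
# parameters, forward, backward


def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def glorot(n_in, n_out):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out))

    return {
        "W1": glorot(cfg.in_dim, cfg.hidden_dim),
        "b1": np.zeros(cfg.hidden_dim),
        "W2": glorot(cfg.hidden_dim, cfg.hidden_dim),
        "b2": np.zeros(cfg.hidden_dim),
        "W3": glorot(cfg.pooled_dim, cfg.dense_dim),
        "b3": np.zeros(cfg.dense_dim),
        "W4": glorot(cfg.dense_dim, cfg.out_dim),
        "b4": np.zeros(cfg.out_dim),
    }


def _leaky(x: np.ndarray, s: float) -> np.ndarray:
    return np.where(x > 0, x, s * x)


def _leaky_grad(x: np.ndarray, s: float) -> np.ndarray:
    return np.where(x > 0, 1.0, s)


def _forward_batch(params, batch: _Batch, slope: float, want_cache: bool = False):
    z1 = batch.m0 @ params["W1"] + params["b1"]
    h1 = _leaky(z1, slope)
    m1 = batch.a @ h1
    z2 = m1 @ params["W2"] + params["b2"]
    h2 = _leaky(z2, slope)

    nb = len(batch.slices)
    hdim = h2.shape[1]
    pooled = np.empty((nb, 2 * hdim))
    argmax = np.empty((nb, hdim), dtype=np.int64)
    for gi, sl in enumerate(batch.slices):
        block = h2[sl]
        pooled[gi, :hdim] = block.mean(axis=0)
        am = block.argmax(axis=0)
        argmax[gi] = am + sl.start
        pooled[gi, hdim:] = block[am, np.arange(hdim)]

    z3 = pooled @ params["W3"] + params["b3"]
    h3 = _leaky(z3, slope)
    yhat = (h3 @ params["W4"] + params["b4"]).ravel()
    if not want_cache:
        return yhat, None
    return yhat, {
        "z1": z1, "h1": h1, "m1": m1, "z2": z2, "h2": h2,
        "pooled": pooled, "argmax": argmax, "z3": z3, "h3": h3,
    }


def _backward_batch(params, batch: _Batch, cache, yhat, slope: float):
    nb = yhat.size
    resid = yhat - batch.y
    rmse = float(np.sqrt(np.mean(resid**2)))
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    if rmse == 0.0:
        return rmse, grads

    dyhat = (resid / (nb * rmse)).reshape(-1, 1)

    grads["W4"] = cache["h3"].T @ dyhat
    grads["b4"] = dyhat.sum(axis=0)
    dh3 = dyhat @ params["W4"].T
    dz3 = dh3 * _leaky_grad(cache["z3"], slope)
    grads["W3"] = cache["pooled"].T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    dpooled = dz3 @ params["W3"].T

    hdim = cache["h2"].shape[1]
    dh2 = np.zeros_like(cache["h2"])
    cols = np.arange(hdim)
    for gi, sl in enumerate(batch.slices):
        n = sl.stop - sl.start
        dh2[sl] += dpooled[gi, :hdim] / n
        np.add.at(dh2, (cache["argmax"][gi], cols), dpooled[gi, hdim:])

    dz2 = dh2 * _leaky_grad(cache["z2"], slope)
    grads["W2"] = cache["m1"].T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dm1 = dz2 @ params["W2"].T
    dh1 = batch.a.T @ dm1
    dz1 = dh1 * _leaky_grad(cache["z1"], slope)
    grads["W1"] = batch.m0.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return rmse, grads


class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# public model object


@dataclass
class TrainedModel:
    """Frozen weights plus everything needed to reapply them."""

    params: dict[str, np.ndarray]
    config: ModelConfig
    schema: NodeFeatureSchema
    training_log: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def predict(self, graphs: Sequence[ReactionGraph]) -> np.ndarray:
        """Predicted %top for each graph."""
        preps = prepare_graphs(graphs)
        if not preps:
            return np.empty(0)
        batch = _Batch(preps)
        yhat, _ = _forward_batch(batch=batch, params=self.params,
                                 slope=self.config.leaky_slope)
        return yhat

    def pooled_vector(self, g: ReactionGraph) -> np.ndarray:
        """Graph-level [mean ‖ max] embedding (length pooled_dim)."""
        batch = _Batch(prepare_graphs([g]))
        _, cache = _forward_batch(self.params, batch,
                                  self.config.leaky_slope, want_cache=True)
        return cache["pooled"][0]

    def save(self, path: str | Path) -> None:
        blob = {
            "params": {k: v.tolist() for k, v in self.params.items()},
            "config": asdict(self.config),
            "schema": self.schema.to_dict(),
            "training_log": self.training_log,
            "best_epoch": self.best_epoch,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            params={k: np.asarray(v) for k, v in blob["params"].items()},
            config=ModelConfig(**blob["config"]),
            schema=NodeFeatureSchema.from_dict(blob["schema"]),
            training_log=blob["training_log"],
            best_epoch=blob["best_epoch"],
        )


def forward(g: ReactionGraph, model: TrainedModel) -> float:
    """Predicted %top for one reaction graph."""
    return float(model.predict([g])[0])


def train(
    train_graphs: Sequence[ReactionGraph],
    val_graphs: Sequence[ReactionGraph],
    cfg: ModelConfig,
    schema: NodeFeatureSchema = DEFAULT_SCHEMA,
) -> TrainedModel:
    """Fit the regressor with Adam + plateau LR decay + early stopping.

    The training set is reshuffled every epoch and delivered in batches
    of ``cfg.batch_size`` (last batch smaller); weights update after
    every batch.  Returns the weights of the epoch with the lowest
    validation RMSE.
    """
    if not len(train_graphs) or not len(val_graphs):
        raise ValueError("train and validation sets must both be non-empty")
    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng)
    adam = _Adam(params)
    sched = PlateauLR(cfg.lr_init, cfg.lr_factor, cfg.lr_patience_epochs, cfg.lr_min)
    stopper = EarlyStopping(cfg.early_stop_patience_epochs)

    tr = prepare_graphs(train_graphs)
    val_batch = _Batch(prepare_graphs(val_graphs))
    n = len(tr)

    log: list[dict] = []
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    best_epoch = 0
    lr = sched.lr

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = _Batch([tr[i] for i in idx])
            yhat, cache = _forward_batch(params, batch, cfg.leaky_slope,
                                         want_cache=True)
            rmse, grads = _backward_batch(params, batch, cache, yhat,
                                          cfg.leaky_slope)
            if not np.isfinite(rmse):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            adam.step(params, grads, lr)
            batch_losses.append(rmse)

        val_pred, _ = _forward_batch(params, val_batch, cfg.leaky_slope)
        val_rmse = float(np.sqrt(np.mean((val_pred - val_batch.y) ** 2)))
        if not np.isfinite(val_rmse):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        log.append(
            {
                "epoch": epoch,
                "train_rmse": float(np.mean(batch_losses)),
                "val_rmse": val_rmse,
                "lr": lr,
            }
        )
        if val_rmse < best_val:
            best_val = val_rmse
            best_params = {k: v.copy() for k, v in params.items()}
            best_epoch = epoch
        lr = sched.step(val_rmse)
        if stopper.step(val_rmse):
            break

    return TrainedModel(
        params=best_params,
        config=cfg,
        schema=schema,
        training_log=log,
        best_epoch=best_epoch,
    )
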