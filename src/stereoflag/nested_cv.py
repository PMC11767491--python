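"""Nested k-fold cross-validation engine.

With k folds, each fold serves once as the test set; within each test
fold, each of the remaining k-1 folds serves once as the validation set
while the other k-2 folds train the model.  That yields k(k-1) training
processes (90 for k=10) and k-1 independent test predictions per
reaction, which downstream outlier voting consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .dataset_io import Dataset
from .featurization import ReactionGraph
from . import gnn

__all__ = ["FoldPlan", "make_folds", "run_nested_cv", "summarize", "process_seed"]

PREDICTION_COLUMNS = (
    "reaction_id", "test_fold", "val_fold", "label", "prediction", "abs_error",
)


@dataclass(frozen=True)
class FoldPlan:
    """Seeded assignment of every reaction to exactly one of k folds."""

    k: int
    assignment: Mapping[int, int]  # reaction_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list[int]:
        return [rid for rid, f in self.assignment.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": list(self.assignment), "fold": list(self.assignment.values())}
        )


def make_folds(
    ds: Dataset | Sequence[int], k: int, seed: int, group_by_ligand: bool = False
) -> FoldPlan:
    """Random near-equal partition of the dataset into k folds.

    Fold sizes differ by at most one.  With ``group_by_ligand`` (off by
    default) all reactions sharing a ligand SMILES land in one fold,
    preventing enantiomer/ligand leakage across the test boundary.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if isinstance(ds, Dataset):
        ids = ds.reaction_ids
        ligands = {r.reaction_id: r.ligand_smiles for r in ds}
    else:
        ids = list(ds)
        ligands = None
        group_by_ligand = False
    if len(ids) < k:
        raise ValueError(f"dataset of {len(ids)} records cannot fill {k} folds")

    rng = np.random.default_rng(seed)
    assignment: dict[int, int] = {}
    if not group_by_ligand:
        order = rng.permutation(len(ids))
        for pos, oi in enumerate(order):
            assignment[ids[oi]] = pos % k
    else:
        groups: dict[str, list[int]] = {}
        for rid in ids:
            groups.setdefault(ligands[rid], []).append(rid)
        keys = list(groups)
        # largest groups first onto the currently smallest fold
        order = rng.permutation(len(keys))
        keys = sorted((keys[i] for i in order), key=lambda s: -len(groups[s]))
        sizes = [0] * k
        for key in keys:
            f = int(np.argmin(sizes))
            for rid in groups[key]:
                assignment[rid] = f
            sizes[f] += len(groups[key])
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def process_seed(global_seed: int, test_fold: int, val_fold: int) -> int:
    """Deterministic per-process seed for the (test, val) training run."""
    return (global_seed * 1_000_003 + test_fold * 1009 + val_fold * 101) % (2**31)


def run_nested_cv(
    graphs: Sequence[ReactionGraph],
    plan: FoldPlan,
    cfg: "gnn.ModelConfig",
    trainer: Callable | None = None,
    on_process: Callable | None = None,
    skip: set[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Run all k(k-1) training processes and collect test predictions.

    Parameters
    ----------
    graphs:
        One featurized graph per reaction in the plan.
    trainer:
        ``trainer(train_graphs, val_graphs, cfg) -> model`` with a
        ``model.predict(graphs) -> array`` method; defaults to
        :func:`stereoflag.gnn.train`.  Injectable so the engine can be
        exercised with trivial stand-in models.
    on_process:
        Optional callback ``on_process(test_fold, val_fold, model,
        cell_df)`` for artifact persistence (training logs, checkpoints,
        per-process predictions).
    skip:
        (test_fold, val_fold) cells to leave out, e.g. because a resumed
        run already holds their predictions.

    Returns the prediction table: one row per (reaction, test_fold,
    val_fold) with the prediction and absolute error.  A failed training
    process is recorded in ``df.attrs["failures"]`` and its cell left
    missing rather than aborting the sweep.
    """
    trainer = trainer or gnn.train
    by_id = {g.reaction_id: g for g in graphs}
    missing = [rid for rid in plan.assignment if rid not in by_id]
    if missing:
        raise ValueError(f"no graph for reaction ids {missing[:5]}")

    fold_graphs = {f: [by_id[r] for r in plan.fold_ids(f)] for f in range(plan.k)}
    skip = skip or set()
    rows = []
    failures = []
    for t in range(plan.k):
        test = fold_graphs[t]
        for v in range(plan.k):
            if v == t or (t, v) in skip:
                continue
            train_set = [
                g for f in range(plan.k) if f not in (t, v) for g in fold_graphs[f]
            ]
            val_set = fold_graphs[v]
            run_cfg = gnn.ModelConfig(
                **{**cfg.__dict__, "seed": process_seed(cfg.seed, t, v)}
            ) if isinstance(cfg, gnn.ModelConfig) else cfg
            try:
                model = trainer(train_set, val_set, run_cfg)
                preds = np.asarray(model.predict(test), dtype=float)
            except Exception as exc:  # keep the sweep alive; cell goes missing
                failures.append({"test_fold": t, "val_fold": v, "error": str(exc)})
                continue
            cell = [
                {
                    "reaction_id": g.reaction_id,
                    "test_fold": t,
                    "val_fold": v,
                    "label": g.target,
                    "prediction": float(p),
                    "abs_error": abs(float(p) - g.target),
                }
                for g, p in zip(test, preds)
            ]
            rows.extend(cell)
            if on_process is not None:
                on_process(t, v, model, pd.DataFrame(cell, columns=list(PREDICTION_COLUMNS)))
    df = pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS))
    df.attrs["failures"] = failures
    return df


def summarize(pt: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-reaction ensemble means and global parity metrics.

    Each reaction's k-1 test predictions are averaged (fewer if some
    processes failed); RMSE/MAE/R² are computed over these per-reaction
    means, which is what the parity plot shows.
    """
    if pt.empty:
        raise ValueError("prediction table is empty")
    per = (
        pt.groupby("reaction_id")
        .agg(
            label=("label", "first"),
            mean_prediction=("prediction", "mean"),
            n_predictions=("prediction", "size"),
        )
        .reset_index()
    )
    per["abs_error"] = (per["mean_prediction"] - per["label"]).abs()
    resid = per["mean_prediction"] - per["label"]
    metrics = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        # R^2 needs at least two reactions to be defined
        "r2": float(r2_score(per["label"], per["mean_prediction"]))
        if len(per) > 1 else float("nan"),
        "n_reactions": int(len(per)),
    }
    return per, metrics
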