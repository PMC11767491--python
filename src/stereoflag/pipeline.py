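"""End-to-end orchestration: featurize → nested CV → detect → report.

A run is driven by a :class:`RunConfig` and leaves a self-describing
artifact bundle in the output directory:

    fold_plan.csv            reaction_id -> fold
    processes/t<T>_v<V>.predictions.csv   per-process test predictions
    processes/t<T>_v<V>.training_log.csv  per-epoch train/val loss + lr
    predictions.csv          the full prediction table
    parity.csv               per-reaction ensemble mean vs label
    metrics.json             RMSE / MAE / R² of the ensemble means
    outlier_report.csv       votes and flags per reaction
    curation_table.csv       flagged reactions, ranked
    summary.json             headline counts and fractions
    manifest.json            config + seeds + versions (reproducibility)

Interrupted sweeps resume at (test_fold, val_fold) granularity: cells
whose prediction CSV already exists are not retrained.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset_io import Dataset, load_dataset, augment_with_enantiomeric_ligands
from .featurization import DEFAULT_SCHEMA, NodeFeatureSchema, build_reaction_graph
from .gnn import ModelConfig
from .nested_cv import FoldPlan, make_folds, run_nested_cv, summarize
from .outliers import OutlierCriterion, detect_outliers, curation_report

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs."""

    dataset_path: str | Path | None = None
    out_dir: str | Path = "stereoflag_run"
    model: ModelConfig = field(default_factory=ModelConfig)
    k: int = 10
    criterion: OutlierCriterion = field(default_factory=OutlierCriterion)
    vote_threshold: int = 5
    seed: int = 0
    augment: bool = False
    group_folds_by_ligand: bool = False
    dialect: dict | None = None

    def __post_init__(self) -> None:
        if self.k - 1 < self.vote_threshold:
            raise ValueError(
                f"k-1={self.k - 1} processes cannot reach vote_threshold={self.vote_threshold}"
            )

    def to_manifest(self) -> dict:
        import rdkit

        return {
            "stereoflag_version": __version__,
            "numpy_version": np.__version__,
            "rdkit_version": rdkit.__version__,
            "python_version": platform.python_version(),
            "dataset_path": str(self.dataset_path),
            "k": self.k,
            "seed": self.seed,
            "vote_threshold": self.vote_threshold,
            "augment": self.augment,
            "group_folds_by_ligand": self.group_folds_by_ligand,
            "model": asdict(self.model),
            "criterion": asdict(self.criterion),
        }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run(
    cfg: RunConfig,
    dataset: Dataset | None = None,
    schema: NodeFeatureSchema = DEFAULT_SCHEMA,
    dry_run: bool = False,
    resume: bool = False,
) -> dict:
    """Execute the pipeline; returns the summary dict.

    ``dataset`` may be passed directly (e.g. a synthetic one); otherwise
    it is loaded from ``cfg.dataset_path``.  With ``dry_run`` the config
    and dataset are validated and the workload scheduled but no model is
    trained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proc_dir = out / "processes"
    proc_dir.mkdir(exist_ok=True)
    manifest = cfg.to_manifest()

    try:
        if dataset is None:
            if cfg.dataset_path is None:
                raise ValueError("RunConfig.dataset_path not set and no dataset passed")
            dataset = load_dataset(cfg.dataset_path, dialect=cfg.dialect)
        if cfg.augment:
            dataset, skipped = augment_with_enantiomeric_ligands(dataset)
            manifest["augmentation_skipped_ids"] = skipped
        if not dataset.rejections.empty:
            dataset.rejections.to_csv(out / "rejections.csv", index=False)

        graphs = [build_reaction_graph(rec, schema) for rec in dataset]
        plan = make_folds(dataset, cfg.k, cfg.seed,
                          group_by_ligand=cfg.group_folds_by_ligand)
        plan.to_frame().to_csv(out / "fold_plan.csv", index=False)
        manifest["n_reactions"] = len(dataset)
        manifest["n_processes_scheduled"] = cfg.k * (cfg.k - 1)

        if dry_run:
            manifest["dry_run"] = True
            _write_json(out / "manifest.json", manifest)
            return {"dry_run": True, "n_reactions": len(dataset),
                    "n_processes_scheduled": cfg.k * (cfg.k - 1)}

        def persist(t: int, v: int, model, cell_df: pd.DataFrame) -> None:
            stem = proc_dir / f"t{t}_v{v}"
            cell_df.to_csv(f"{stem}.predictions.csv", index=False)
            pd.DataFrame(model.training_log).to_csv(
                f"{stem}.training_log.csv", index=False
            )

        skip: set[tuple[int, int]] = set()
        prior: list[pd.DataFrame] = []
        if resume:
            for f in proc_dir.glob("t*_v*.predictions.csv"):
                t, v = (int(x[1:]) for x in f.stem.split(".")[0].split("_"))
                skip.add((t, v))
                prior.append(pd.read_csv(f))

        run_cfg = ModelConfig(**{**cfg.model.__dict__, "seed": cfg.seed})
        pt = run_nested_cv(graphs, plan, run_cfg, on_process=persist, skip=skip)
        if prior:
            frames = [f for f in prior + [pt] if not f.empty]
            pt = pd.concat(frames, ignore_index=True).sort_values(
                ["test_fold", "val_fold", "reaction_id"]
            ).reset_index(drop=True)
        pt.to_csv(out / "predictions.csv", index=False)

        parity, metrics = summarize(pt)
        parity.to_csv(out / "parity.csv", index=False)
        _write_json(out / "metrics.json", metrics)

        report = detect_outliers(pt, cfg.criterion, cfg.vote_threshold)
        report.to_csv(out / "outlier_report.csv", index=False)
        table, flag_summary = curation_report(report, dataset)
        table.to_csv(out / "curation_table.csv", index=False)

        summary = {
            **flag_summary,
            "flagged_pct": 100.0 * flag_summary["flagged_fraction"],
            "metrics": metrics,
            "n_processes_completed": cfg.k * (cfg.k - 1)
            - len(pt.attrs.get("failures", [])),
            "failures": pt.attrs.get("failures", []),
        }
        _write_json(out / "summary.json", summary)
        manifest["status"] = "ok"
        _write_json(out / "manifest.json", manifest)
        return summary
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        _write_json(out / "manifest.json", manifest)
        raise
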