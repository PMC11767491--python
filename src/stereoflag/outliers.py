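"""Residual-based outlier criterion and ensemble voting.

Per training process, a test reaction is an outlier when its absolute
prediction error stands out against the other errors of the same test
set: with the default mean-centered criterion,

    e_i - mean(e) > 3 * SD(e),

the SD taken over all errors of that process (candidate included).  The
centering is what makes a uniformly poor model produce zero outliers —
only relatively extreme errors are flagged.  Across the k-1 processes of
a reaction's test fold, the flags are counted; a reaction mis-predicted
by a majority of models (>= 5 of 9 by default) is reported as a
suspected stereochemical misassignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import Dataset

__all__ = [
    "OutlierCriterion",
    "flag_outliers_one_process",
    "count_votes",
    "vote",
    "detect_outliers",
    "curation_report",
]

REPORT_COLUMNS = ("reaction_id", "times_as_outlier", "n_processes", "flagged")


@dataclass(frozen=True)
class OutlierCriterion:
    """The per-process residual threshold.

    sd_multiplier:
        how many standard deviations beyond the reference point an
        error must lie (3.0 in the reference procedure).
    centering:
        "mean" (default) flags e_i when e_i - mean(e) > mult*SD(e);
        "none" flags when e_i > mult*SD(e) (the literal uncentered
        reading).
    sd_kind:
        "population" (ddof=0, default) or "sample" (ddof=1).
    """

    sd_multiplier: float = 3.0
    centering: str = "mean"
    sd_kind: str = "population"

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.centering not in ("mean", "none"):
            raise ValueError("centering must be 'mean' or 'none'")
        if self.sd_kind not in ("population", "sample"):
            raise ValueError("sd_kind must be 'population' or 'sample'")


def flag_outliers_one_process(
    errors: Sequence[float], crit: OutlierCriterion = OutlierCriterion()
) -> np.ndarray:
    """Boolean outlier flags for one process's test-set errors."""
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("criterion needs at least 2 errors to define an SD")
    sd = e.std(ddof=0 if crit.sd_kind == "population" else 1)
    if crit.centering == "mean":
        return (e - e.mean()) > crit.sd_multiplier * sd
    return e > crit.sd_multiplier * sd


def count_votes(pt: pd.DataFrame, crit: OutlierCriterion = OutlierCriterion()) -> pd.DataFrame:
    """Apply the criterion per (test_fold, val_fold) process and count flags.

    Returns one row per reaction: times_as_outlier and the number of
    processes in which it received a prediction.
    """
    parts = []
    for (t, v), grp in pt.groupby(["test_fold", "val_fold"]):
        flags = flag_outliers_one_process(grp["abs_error"].to_numpy(), crit)
        parts.append(pd.DataFrame({"reaction_id": grp["reaction_id"], "flag": flags}))
    allf = pd.concat(parts, ignore_index=True)
    counts = (
        allf.groupby("reaction_id")
        .agg(times_as_outlier=("flag", "sum"), n_processes=("flag", "size"))
        .reset_index()
    )
    counts["times_as_outlier"] = counts["times_as_outlier"].astype(int)
    return counts


def vote(counts: pd.DataFrame, vote_threshold: int = 5) -> pd.DataFrame:
    """Majority vote: flagged iff times_as_outlier >= vote_threshold."""
    out = counts.copy()
    out["flagged"] = out["times_as_outlier"] >= vote_threshold
    short = out["n_processes"] < out["n_processes"].max()
    if short.any():
        out.attrs["warning"] = (
            f"{int(short.sum())} reactions have fewer processes than the rest "
            "(failed trainings); the vote threshold stays absolute"
        )
    return out


def detect_outliers(
    pt: pd.DataFrame,
    crit: OutlierCriterion = OutlierCriterion(),
    vote_threshold: int = 5,
) -> pd.DataFrame:
    """Full detection: per-process 3σ flags, then the ensemble vote."""
    return vote(count_votes(pt, crit), vote_threshold)


def curation_report(
    report: pd.DataFrame, ds: Dataset | None = None
) -> tuple[pd.DataFrame, dict]:
    """Ranked table of flagged reactions plus a headline summary.

    Flagged reactions are sorted by vote count (desc) then reaction_id;
    the summary carries the flagged count and the flagged fraction of
    the dataset — the quantity that measures how much manual curation
    the ensemble saves.
    """
    table = report[report["flagged"]].sort_values(
        ["times_as_outlier", "reaction_id"], ascending=[False, True]
    ).reset_index(drop=True)
    if ds is not None:
        meta = {
            r.reaction_id: (r.ligand_smiles, r.source_ref, r.is_virtual) for r in ds
        }
        table = table.assign(
            ligand_smiles=[meta[r][0] for r in table["reaction_id"]],
            source_ref=[meta[r][1] for r in table["reaction_id"]],
            is_virtual=[meta[r][2] for r in table["reaction_id"]],
        )
    n_total = len(ds) if ds is not None else int(report["reaction_id"].nunique())
    n_flagged = int(len(table))
    summary = {
        "n_total": n_total,
        "n_flagged": n_flagged,
        "flagged_fraction": n_flagged / n_total if n_total else 0.0,
    }
    return table, summary
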