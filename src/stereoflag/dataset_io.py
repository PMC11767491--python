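"""Reaction dataset I/O, the %top target, and enantiomer augmentation.

A reaction record couples three component molecules — chiral ligand,
Michael-acceptor substrate and organoboron reagent — with the facial
selectivity outcome ``%top``: the percentage of nucleophile addition to
the "top" prochiral face of the acceptor (50 = racemic, >50 means the
"top" isomer is the major product).

Datasets live on disk as plain CSV.  Loading never aborts on a bad row:
rows with unparseable SMILES or an out-of-range ``%top`` are collected
into a machine-readable rejection report attached to the returned
:class:`Dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "ReactionRecord",
    "Dataset",
    "DatasetError",
    "ConfigurationError",
    "CANONICAL_COLUMNS",
    "load_dataset",
    "save_dataset",
    "pct_top_from_er",
    "mirror_ligand_smiles",
    "augment_with_enantiomeric_ligands",
]

CANONICAL_COLUMNS = (
    "reaction_id",
    "ligand_smiles",
    "substrate_smiles",
    "reagent_smiles",
    "pct_top",
    "source_ref",
    "is_virtual",
)

_REQUIRED = CANONICAL_COLUMNS[:5]


class DatasetError(ValueError):
    """Raised when a dataset is empty or structurally invalid."""


class ConfigurationError(ValueError):
    """Raised for bad column maps / malformed configuration."""


@dataclass(frozen=True)
class ReactionRecord:
    """One literature (or virtual) reaction exemplar."""

    reaction_id: int
    ligand_smiles: str
    substrate_smiles: str
    reagent_smiles: str
    pct_top: float
    source_ref: str = ""
    is_virtual: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.pct_top <= 100.0:
            raise DatasetError(
                f"reaction {self.reaction_id}: pct_top={self.pct_top} outside [0, 100]"
            )
        for role in ("ligand", "substrate", "reagent"):
            smi = getattr(self, f"{role}_smiles")
            if Chem.MolFromSmiles(smi) is None:
                raise DatasetError(
                    f"reaction {self.reaction_id}: {role} SMILES does not parse: {smi!r}"
                )


@dataclass
class Dataset:
    """An ordered collection of reaction records with unique ids."""

    records: list[ReactionRecord]
    name: str = "dataset"
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "reason"])
    )

    def __post_init__(self) -> None:
        if not self.records:
            raise DatasetError(f"dataset {self.name!r} has no valid records")
        ids = [r.reaction_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate reaction_id values: {dupes[:10]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReactionRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ReactionRecord:
        return self.records[i]

    @property
    def reaction_ids(self) -> list[int]:
        return [r.reaction_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=CANONICAL_COLUMNS)


def pct_top_from_er(er_top: float, er_bottom: float) -> float:
    """%top from an enantiomeric ratio expressed as (top : bottom).

    ``%top = 100 * er_top / (er_top + er_bottom)``, so e.g. an er of
    95:5 in favour of the top isomer gives 95.0.
    """
    if er_top < 0 or er_bottom < 0:
        raise ValueError("enantiomeric-ratio components must be non-negative")
    total = er_top + er_bottom
    if total == 0:
        raise ValueError("er_top + er_bottom must be positive")
    return 100.0 * er_top / total


def load_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
) -> Dataset:
    """Load a reaction dataset from CSV.

    Parameters
    ----------
    path:
        CSV file with (at least) the canonical columns, possibly under
        different names.
    dialect:
        Optional map from canonical column name to the name used in the
        file, e.g. ``{"pct_top": "%top"}``.
    name:
        Dataset name; defaults to the file stem.

    Rows that fail validation (unparseable SMILES, ``pct_top`` outside
    [0, 100], non-numeric id/target) are recorded in
    ``Dataset.rejections`` (columns ``row``, ``reason``; ``row`` is the
    1-based data row number) rather than silently dropped.
    """
    path = Path(path)
    dialect = dict(dialect or {})
    # round_trip parsing keeps save -> load exact on float labels
    raw = pd.read_csv(path, float_precision="round_trip")

    rename = {v: k for k, v in dialect.items()}
    raw = raw.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required columns {missing}; present: {list(raw.columns)}"
        )
    if "source_ref" not in raw.columns:
        raw["source_ref"] = ""
    if "is_virtual" not in raw.columns:
        raw["is_virtual"] = False

    records: list[ReactionRecord] = []
    rejections: list[dict] = []
    for pos, row in enumerate(raw.itertuples(index=False), start=1):
        try:
            rec = ReactionRecord(
                reaction_id=int(row.reaction_id),
                ligand_smiles=str(row.ligand_smiles),
                substrate_smiles=str(row.substrate_smiles),
                reagent_smiles=str(row.reagent_smiles),
                pct_top=float(row.pct_top),
                source_ref="" if pd.isna(row.source_ref) else str(row.source_ref),
                is_virtual=bool(row.is_virtual),
            )
            rec.validate()
        except (DatasetError, TypeError, ValueError) as exc:
            rejections.append({"row": pos, "reason": str(exc)})
            continue
        records.append(rec)

    if not records:
        raise DatasetError(f"{path}: zero valid rows ({len(rejections)} rejected)")
    ds = Dataset(records, name=name or path.stem)
    ds.rejections = pd.DataFrame(rejections, columns=["row", "reason"])
    return ds


def save_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset to CSV in the canonical column layout."""
    ds.to_frame().to_csv(path, index=False)


def mirror_ligand_smiles(smiles: str) -> str | None:
    """SMILES of the mirror-image molecule, or None if achiral-as-written.

    Every tetrahedral chiral tag is inverted; double-bond (E/Z) geometry
    is left untouched because reflection preserves it.  Returns ``None``
    when the SMILES carries no invertible tetrahedral descriptor, i.e.
    the written structure is its own mirror image at this level of
    description (axial chirality is not expressible here and needs a
    pre-mirrored SMILES entered by hand).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DatasetError(f"ligand SMILES does not parse: {smiles!r}")
    inverted = False
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            inverted = True
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            inverted = True
    if not inverted:
        return None
    return Chem.MolToSmiles(mol)


def augment_with_enantiomeric_ligands(
    ds: Dataset,
) -> tuple[Dataset, list[int]]:
    """Append one virtual enantiomeric reaction per real record.

    For each real record, a virtual twin is created whose ligand is the
    mirror image and whose label is ``100 - pct_top`` (the facial
    selection of the mirror catalyst on a prochiral substrate is the
    mirror outcome).  Virtual records get fresh ids after the current
    maximum and ``is_virtual=True``.

    Returns the augmented dataset and the list of reaction_ids whose
    ligand carried no invertible stereocenter (skipped, not mirrored).
    """
    next_id = max(ds.reaction_ids) + 1
    out = list(ds.records)
    skipped: list[int] = []
    for rec in ds.records:
        if rec.is_virtual:
            continue
        mirrored = mirror_ligand_smiles(rec.ligand_smiles)
        if mirrored is None:
            skipped.append(rec.reaction_id)
            continue
        out.append(
            replace(
                rec,
                reaction_id=next_id,
                ligand_smiles=mirrored,
                pct_top=100.0 - rec.pct_top,
                is_virtual=True,
            )
        )
        next_id += 1
    aug = Dataset(out, name=f"{ds.name}+enantiomers")
    aug.rejections = ds.rejections
    return aug, skipped
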