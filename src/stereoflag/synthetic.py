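"""Synthetic reaction datasets with a planted selectivity rule and flips.

The generator emulates the structure of a curated asymmetric 1,4-addition
database: every reaction couples a chiral ligand, a Michael acceptor and
an organoboron reagent with a %top outcome.  The planted physics is the
simplest caricature of the real stereochemical logic — the ligand's
absolute configuration and the substrate's cyclicity jointly set the
favoured face:

    %top = 50 + rule_strength * s * c + N(0, noise_sd),  clipped to [0,100]

with s = +1 for an R-configured ligand stereocenter, -1 for S, and
c = +1 for cyclic acceptors, -1 for acyclic.  A seeded fraction of
records then has its label inverted to 100 - %top, standing in for
literature stereochemical misassignments; the flipped ids are returned
as ground truth so recovery can be scored.

Ligands are generated as exact enantiomeric pairs of small one-
stereocenter scaffolds, so CIP labels are well defined and mirror pairs
differ only in their stereo descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .dataset_io import Dataset, ReactionRecord

__all__ = ["SyntheticSpec", "RecoveryMetrics", "generate", "evaluate_recovery",
           "ligand_configuration"]

# substituent fragments for the chiral ligand scaffold C[C@H](a)(b);
# all draw on the B,C,N,O,F,P,S element vocabulary
_SUBSTITUENTS = (
    "CC", "CCC", "CC(C)C", "c1ccccc1", "c1ccc(F)cc1", "CO", "OC",
    "N(C)C", "CCO", "c1ccco1", "CSC", "CP(C)C",
)

_CYCLIC_SUBSTRATES = (
    "O=C1CCCC=C1",        # cyclohex-2-en-1-one
    "O=C1CCC=C1",         # cyclopent-2-en-1-one
    "O=C1CCCCC=C1",       # cyclohept-2-en-1-one
    "O=C1CCCC(C)=C1",
    "O=C1CCC(C)C=C1",
    "O=C1COCC=C1",
    "O=C1CCCC=C1C",
    "O=C1CC(C)CC=C1",
)

# acyclic acceptors kept ring-free so substrate cyclicity is expressed
# purely in the ring-membership features
_ACYCLIC_SUBSTRATES = (
    "CC(=O)/C=C/C",
    "CCC(=O)/C=C/C",
    "CC(=O)/C=C/CC",
    "COC(=O)/C=C/C",
    "CC(=O)/C=C/C(C)C",
    "CCCC(=O)/C=C/C",
    "CC(=O)/C=C/CO",
    "CCOC(=O)/C=C/C",
)

_REAGENTS = (
    "OB(O)c1ccccc1",
    "OB(O)c1ccc(C)cc1",
    "OB(O)c1ccc(F)cc1",
    "OB(O)c1ccc(OC)cc1",
    "OB(O)c1cccc(C)c1",
    "OB(O)c1ccc(CC)cc1",
    "OB(O)/C=C/C",
    "OB(O)c1ccco1",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the desk-scale benchmark conditions: 400 reactions, a
    45-unit planted displacement from racemic, 5 units of Gaussian
    noise, and 3% of labels inverted.
    """

    n_ligands: int = 12
    n_substrates: int = 10
    n_reagents: int = 8
    n_reactions: int = 400
    rule_strength: float = 45.0
    noise_sd: float = 5.0
    flip_fraction: float = 0.03
    cyclic_substrate_fraction: float = 0.5
    cluster_flips_by_ligand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rule_strength <= 50:
            raise ValueError("rule_strength must be in (0, 50]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.flip_fraction <= 0.2:
            raise ValueError("flip_fraction must be in [0, 0.2]")
        if not 0 <= self.cyclic_substrate_fraction <= 1:
            raise ValueError("cyclic_substrate_fraction must be in [0, 1]")
        if self.n_ligands < 2 or self.n_ligands % 2:
            raise ValueError("n_ligands must be an even number >= 2")


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the flagged set recovers the planted label flips."""

    recall: float
    precision: float
    false_flag_rate: float
    n_flips: int
    n_flagged: int
    n_true_positives: int


def ligand_configuration(smiles: str) -> int:
    """+1 for an R stereocenter, -1 for S, 0 if none assigned."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES does not parse: {smiles!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    for atom in mol.GetAtoms():
        cip = atom.GetPropsAsDict().get("_CIPCode")
        if cip == "R":
            return 1
        if cip == "S":
            return -1
    return 0


def _ligand_library(n_ligands: int, rng: np.random.Generator) -> list[str]:
    """Enantiomeric pairs of one-stereocenter scaffolds C[C*H](a)b."""
    pairs = [
        (a, b) for a, b in combinations(_SUBSTITUENTS, 2)
    ]
    order = rng.permutation(len(pairs))
    lib: list[str] = []
    for oi in order:
        if len(lib) >= n_ligands:
            break
        a, b = pairs[oi]
        for tag in ("@", "@@"):
            smi = f"C[C{tag}H]({a}){b}"
            if ligand_configuration(smi) == 0:
                # substituent pair failed to make a genuine stereocenter
                lib = lib[: len(lib) - len(lib) % 2]
                break
            lib.append(smi)
    if len(lib) < n_ligands:
        raise ValueError(
            f"scaffold pool exhausted: built {len(lib)} of {n_ligands} ligands"
        )
    return lib[:n_ligands]


def generate(spec: SyntheticSpec) -> tuple[Dataset, set[int]]:
    """Build a synthetic dataset and the ground-truth set of flipped ids."""
    rng = np.random.default_rng(spec.seed)
    ligands = _ligand_library(spec.n_ligands, rng)
    lig_config = {smi: ligand_configuration(smi) for smi in ligands}

    n_cyc = int(round(spec.cyclic_substrate_fraction * spec.n_substrates))
    n_acyc = spec.n_substrates - n_cyc
    if n_cyc > len(_CYCLIC_SUBSTRATES) or n_acyc > len(_ACYCLIC_SUBSTRATES):
        raise ValueError("requested more substrates than the scaffold pools hold")
    substrates = [
        (str(s), 1) for s in rng.choice(_CYCLIC_SUBSTRATES, n_cyc, replace=False)
    ] + [
        (str(s), -1) for s in rng.choice(_ACYCLIC_SUBSTRATES, n_acyc, replace=False)
    ]
    if spec.n_reagents > len(_REAGENTS):
        raise ValueError("requested more reagents than the pool holds")
    reagents = [str(r) for r in rng.choice(_REAGENTS, spec.n_reagents, replace=False)]

    li = rng.integers(0, len(ligands), spec.n_reactions)
    si = rng.integers(0, len(substrates), spec.n_reactions)
    ri = rng.integers(0, len(reagents), spec.n_reactions)
    noise = rng.normal(0.0, spec.noise_sd, spec.n_reactions)

    records: list[ReactionRecord] = []
    for i in range(spec.n_reactions):
        lig = ligands[li[i]]
        sub, c = substrates[si[i]]
        s = lig_config[lig]
        pct = float(np.clip(50.0 + spec.rule_strength * s * c + noise[i], 0.0, 100.0))
        records.append(
            ReactionRecord(
                reaction_id=i,
                ligand_smiles=lig,
                substrate_smiles=sub,
                reagent_smiles=reagents[ri[i]],
                pct_top=pct,
                source_ref=f"synthetic:seed{spec.seed}",
            )
        )

    n_flips = int(round(spec.flip_fraction * spec.n_reactions))
    if n_flips == 0:
        flip_ids: set[int] = set()
    elif spec.cluster_flips_by_ligand:
        # flips concentrated on as few ligands as needed (mimics lab-level
        # systematic inversion rather than scattered entry errors)
        by_lig: dict[str, list[int]] = {}
        for rec in records:
            by_lig.setdefault(rec.ligand_smiles, []).append(rec.reaction_id)
        pool: list[int] = []
        for key in rng.permutation(sorted(by_lig)):
            pool.extend(by_lig[key])
            if len(pool) >= n_flips:
                break
        flip_ids = set(pool[:n_flips])
    else:
        flip_ids = set(
            int(i) for i in rng.choice(spec.n_reactions, n_flips, replace=False)
        )

    for idx in flip_ids:
        rec = records[idx]
        records[idx] = ReactionRecord(
            **{**vars(rec), "pct_top": 100.0 - rec.pct_top}
        )

    ds = Dataset(records, name=f"synthetic-seed{spec.seed}")
    return ds, flip_ids


def save_truth(flip_ids: set[int], ds: Dataset, path: str | Path) -> None:
    """Ground-truth CSV: reaction_id, flipped."""
    pd.DataFrame(
        {
            "reaction_id": ds.reaction_ids,
            "flipped": [rid in flip_ids for rid in ds.reaction_ids],
        }
    ).to_csv(path, index=False)


def evaluate_recovery(report: pd.DataFrame, truth: set[int]) -> RecoveryMetrics:
    """Score a detection report against the planted flip set.

    recall = flagged flips / flips; precision = flagged flips / flags
    (NaN when nothing is flagged); false_flag_rate = flagged clean
    records / clean records.
    """
    flagged = set(int(r) for r in report.loc[report["flagged"], "reaction_id"])
    all_ids = set(int(r) for r in report["reaction_id"])
    tp = len(flagged & truth)
    n_clean = len(all_ids - truth)
    return RecoveryMetrics(
        recall=tp / len(truth) if truth else float("nan"),
        precision=tp / len(flagged) if flagged else float("nan"),
        false_flag_rate=(len(flagged - truth) / n_clean) if n_clean else float("nan"),
        n_flips=len(truth),
        n_flagged=len(flagged),
        n_true_positives=tp,
    )
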