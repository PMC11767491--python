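"""Molecular-graph featurization: 24-dim one-hot node features per heavy atom.

Each reaction is represented as the disjoint union of its three component
graphs (ligand, substrate, reagent) — no inter-component edges; pooling in
the network later mixes the components into one reaction-level vector.

Node features are six strictly one-hot groups totalling width 24:

======================  =====  =========================================
group                   slots  levels
======================  =====  =========================================
element                 8      B C N O F P S | other
heavy-atom degree       5      0 1 2 3 4+   (hydrogens never counted)
hybridization           4      sp sp2 sp3 | other
aromaticity             2      non-aromatic | aromatic
ring membership         2      acyclic | in-ring
CIP configuration       3      R | S | none
======================  =====  =========================================

Every row therefore sums to exactly 6 (one active slot per group).
Atom order is the canonical order of the parsed molecule, so any SMILES
of the same structure produces the same matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .dataset_io import ReactionRecord

__all__ = [
    "NodeFeatureSchema",
    "ReactionGraph",
    "FeaturizationError",
    "DEFAULT_SCHEMA",
    "featurize_molecule",
    "build_reaction_graph",
]

COMPONENTS = ("ligand", "substrate", "reagent")


class FeaturizationError(ValueError):
    """A SMILES could not be converted to a feature graph."""


_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


@dataclass(frozen=True)
class NodeFeatureSchema:
    """Layout of the one-hot node feature vector.

    The total width must be exactly 24; each categorical group carries an
    explicit catch-all level so encoding is total on any molecule.
    """

    element_vocab: tuple[str, ...] = ("B", "C", "N", "O", "F", "P", "S")
    degree_levels: tuple[int, ...] = (0, 1, 2, 3, 4)  # last level means >= 4
    hybridization_levels: tuple[str, ...] = ("sp", "sp2", "sp3")
    stereo_levels: tuple[str, ...] = ("R", "S", "none")

    def __post_init__(self) -> None:
        if self.width != 24:
            raise ValueError(
                f"node feature width must be 24, schema gives {self.width}"
            )
        if self.stereo_levels != ("R", "S", "none"):
            raise ValueError("stereo group must be (R, S, none)")

    # group sizes: element gets a trailing "other", hybridization too;
    # aromatic and ring are 2-slot one-hots (no / yes).
    @property
    def group_sizes(self) -> tuple[int, ...]:
        return (
            len(self.element_vocab) + 1,
            len(self.degree_levels),
            len(self.hybridization_levels) + 1,
            2,
            2,
            len(self.stereo_levels),
        )

    @property
    def group_names(self) -> tuple[str, ...]:
        return ("element", "degree", "hybridization", "aromatic", "ring", "stereo")

    @property
    def width(self) -> int:
        return sum(self.group_sizes)

    @property
    def group_slices(self) -> dict[str, slice]:
        out: dict[str, slice] = {}
        off = 0
        for name, size in zip(self.group_names, self.group_sizes):
            out[name] = slice(off, off + size)
            off += size
        return out

    def to_dict(self) -> dict:
        return {
            "element_vocab": list(self.element_vocab),
            "degree_levels": list(self.degree_levels),
            "hybridization_levels": list(self.hybridization_levels),
            "stereo_levels": list(self.stereo_levels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NodeFeatureSchema":
        return cls(
            element_vocab=tuple(d["element_vocab"]),
            degree_levels=tuple(d["degree_levels"]),
            hybridization_levels=tuple(d["hybridization_levels"]),
            stereo_levels=tuple(d["stereo_levels"]),
        )

    # --- per-atom encoding -------------------------------------------------

    def encode_atom(self, atom: Chem.Atom) -> np.ndarray:
        row = np.zeros(self.width, dtype=np.float64)
        sl = self.group_slices

        sym = atom.GetSymbol()
        vocab = self.element_vocab
        idx = vocab.index(sym) if sym in vocab else len(vocab)
        row[sl["element"].start + idx] = 1.0

        deg = min(atom.GetDegree(), self.degree_levels[-1])
        row[sl["degree"].start + self.degree_levels.index(deg)] = 1.0

        hyb = _HYB_MAP.get(atom.GetHybridization())
        hlev = self.hybridization_levels
        hidx = hlev.index(hyb) if hyb in hlev else len(hlev)
        row[sl["hybridization"].start + hidx] = 1.0

        row[sl["aromatic"].start + int(atom.GetIsAromatic())] = 1.0
        row[sl["ring"].start + int(atom.IsInRing())] = 1.0

        cip = atom.GetPropsAsDict().get("_CIPCode", "none")
        if cip not in ("R", "S"):
            cip = "none"
        row[sl["stereo"].start + self.stereo_levels.index(cip)] = 1.0
        return row


DEFAULT_SCHEMA = NodeFeatureSchema()


def _canonical_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"SMILES does not parse: {smiles!r}")
    order = np.argsort(Chem.CanonicalRankAtoms(mol, breakTies=True))
    mol = Chem.RenumberAtoms(mol, [int(i) for i in order])
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def featurize_molecule(
    smiles: str, schema: NodeFeatureSchema = DEFAULT_SCHEMA
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """One-hot node-feature matrix and undirected edge list for a molecule.

    Hydrogens stay implicit: one row per heavy atom, in the canonical
    atom order of the parsed molecule, and degree counts heavy neighbours
    only.  CIP labels come from the toolkit's stereo perception;
    unassignable centres encode as "none".
    """
    mol = _canonical_mol(smiles)
    feats = np.stack([schema.encode_atom(a) for a in mol.GetAtoms()])
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return feats, edges


@dataclass
class ReactionGraph:
    """Merged (disjoint-union) graph of one reaction's three components."""

    node_features: np.ndarray  # (n_nodes, 24)
    adjacency: list[tuple[int, int]]  # undirected, i < j, no self-loops
    component_of: np.ndarray  # (n_nodes,) of {"ligand","substrate","reagent"}
    target: float  # %top label
    reaction_id: int = -1

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "target": self.target,
            "nodes": self.node_features.astype(int).tolist(),
            "edges": [list(e) for e in self.adjacency],
            "component_of": self.component_of.tolist(),
        }

    def dump_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))


def build_reaction_graph(
    rec: ReactionRecord, schema: NodeFeatureSchema = DEFAULT_SCHEMA
) -> ReactionGraph:
    """Featurize a reaction's three components into one merged graph.

    Components are concatenated in (ligand, substrate, reagent) order
    with node-index offsets; no edge ever joins two components.
    """
    blocks: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    comp: list[str] = []
    offset = 0
    for role in COMPONENTS:
        smi = getattr(rec, f"{role}_smiles")
        try:
            feats, mol_edges = featurize_molecule(smi, schema)
        except FeaturizationError as exc:
            raise FeaturizationError(
                f"reaction {rec.reaction_id}, {role} component: {exc}"
            ) from exc
        blocks.append(feats)
        edges.extend((i + offset, j + offset) for i, j in mol_edges)
        comp.extend([role] * feats.shape[0])
        offset += feats.shape[0]
    return ReactionGraph(
        node_features=np.vstack(blocks),
        adjacency=edges,
        component_of=np.array(comp),
        target=float(rec.pct_top),
        reaction_id=rec.reaction_id,
    )
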