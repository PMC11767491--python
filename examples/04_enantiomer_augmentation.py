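"""Enantiomer augmentation: the mirror-image ligand flips the outcome.

For a prochiral substrate, running the mirror-image catalyst produces
the mirror-image product, so a virtual reaction with the enantiomeric
ligand and label 100 - %top is physically valid training data.  This
doubles a dataset without new experiments.
"""

from stereoflag import (
    Dataset,
    ReactionRecord,
    augment_with_enantiomeric_ligands,
    pct_top_from_er,
)

# an er of 95:5 for the top isomer is %top = 95
print("er 95:5  ->  %top =", pct_top_from_er(95, 5))

ds = Dataset(
    [
        ReactionRecord(1, "C[C@H](O)c1ccccc1", "O=C1CCCC=C1",
                       "OB(O)c1ccccc1", 95.0, source_ref="paper A"),
        ReactionRecord(2, "C[C@@H](CC)c1ccco1", "CC(=O)/C=C/C",
                       "OB(O)c1ccc(F)cc1", 12.0, source_ref="paper B"),
        ReactionRecord(3, "CCOCC", "O=C1CCCC=C1",
                       "OB(O)c1ccccc1", 50.0, source_ref="achiral control"),
    ]
)

aug, skipped = augment_with_enantiomeric_ligands(ds)
print(f"{len(ds)} real records -> {len(aug)} after augmentation")
print(f"skipped (no invertible stereocenter): reaction ids {skipped}")
for rec in aug:
    tag = "virtual" if rec.is_virtual else "real   "
    print(f"  [{tag}] id {rec.reaction_id}: %top {rec.pct_top:5.1f}  "
          f"ligand {rec.ligand_smiles}")
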