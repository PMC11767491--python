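# stereoflag

Screening of asymmetric-catalysis reaction databases for probable
**stereochemical misassignments**, using an ensemble of small graph
neural networks.

## The problem

Databases of enantioselective reactions — here, Rh-catalyzed 1,4-
additions of organoboron reagents to Michael acceptors — record for
each reaction a chiral ligand, a substrate, a reagent, and the facial
selectivity **%top**: the percentage of nucleophile addition to the
"top" prochiral face of the acceptor, with 50 meaning racemic and
%top > 50 meaning the "top" isomer is the major product (equivalently,
%top = 100·er_top/(er_top + er_bottom) from an enantiomeric ratio).
A stereochemical misassignment — the reported major enantiomer being
actually the minor one, through a primary-literature error or a
transcription slip — inverts the label to 100 − %top. Finding such
entries by hand means re-checking every row against the original
papers. `stereoflag` reduces that to a short ranked list.

## The method

1. **Featurize** each reaction as the disjoint union of its three
   component graphs; each heavy atom carries a 24-wide one-hot vector
   (element, heavy-atom degree, hybridization, aromaticity, ring
   membership, CIP configuration R/S/none).
2. **Train an ensemble under nested cross-validation**: k = 10 folds;
   each fold is the test set once, and within each test fold each of
   the remaining 9 folds validates one training process (the other 8
   train) — k(k−1) = 90 processes, 9 independent test predictions per
   reaction. The regressor is two graph convolutions (24→64→64,
   leaky-ReLU), concatenated mean+max pooling (→128), and two dense
   layers (→64→1), trained with Adam on per-batch RMSE (batches of 40,
   initial LR 0.01, ×0.7 plateau decay with patience 5, floor 1e-8,
   early stopping with patience 30, best-validation weights kept).
3. **Flag outliers and vote**: within one process, reaction *i* is an
   outlier when eᵢ − mean(e) > 3·SD(e) over that test set's absolute
   errors — so a uniformly poor model flags nothing. A reaction flagged
   by **5 or more of its 9** models is reported as a suspected
   misassignment, ranked by vote count.

A flag is a short-list entry for expert adjudication, not an automatic
correction: rare ligands and conformer-driven inversions can also be
flagged. See `docs/methods.md` for assumptions and limitations.

The package also provides **enantiomer augmentation** (each real
reaction spawns a virtual one with the mirror-image ligand and label
100 − %top) and a **synthetic benchmark** that plants a known
ligand-configuration × substrate-cyclicity selectivity rule plus a
seeded fraction of inverted labels, so the whole pipeline's recovery
can be measured against ground truth.

## Worked example

`examples/03_detect_misassignments.py` generates 300 synthetic
reactions with 12 planted label inversions, runs the 90-process nested
CV and the 3σ vote, and scores the result:

```
300 reactions, 12 planted inversions
ensemble parity: RMSE 19.0, MAE 11.4, R2 0.819 over 300 reactions
flagged 10 reactions (3.3% of the dataset):
 reaction_id  times_as_outlier
          42                 8
          81                 9
         114                 8
         203                 8
         236                 8
         267                 8
         278                 8
         280                 8
         287                 7
         289                 8
recall of planted inversions: 0.83; precision: 1.00; false-flag rate on clean records: 0.000
```

Ten of the twelve planted inversions are recovered (each mis-predicted
by 7–9 of its 9 models), no clean record is falsely flagged, and the
manual-checking load drops from 300 rows to 10. The ensemble RMSE is
inflated by the planted flips themselves — exactly the signal the vote
exploits.

Other examples: `01_featurize_a_reaction.py` (the 24-column node
schema), `02_train_a_regressor.py` (a single training run reaching the
injected noise floor), `04_enantiomer_augmentation.py` (mirror-image
virtual reactions).

## Command line

```bash
stereoflag simulate --out data/ --n-reactions 400 --seed 1
stereoflag run --dataset data/dataset.csv --out run/ --k 10 --seed 1
stereoflag detect --predictions run/predictions.csv --out report.csv
```

`stereoflag run` leaves a full artifact bundle (fold plan, 90 training
logs, prediction table, parity summary, outlier report, manifest) and
supports `--dry-run` and `--resume`.

## Reference datasets

The published diene (688 reactions, augmented from 343) and
bisphosphine (644 reactions) databases are distributed as supplementary
material of their paper and are not bundled here. If you place their
CSVs at `data/appendix/diene.csv` and `data/appendix/bisphosphine.csv`
(canonical columns or a dialect map), the test-suite additionally
verifies their record and component counts, and `stereoflag run` works
on them directly.
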