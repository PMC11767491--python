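# Methods

`stereoflag` screens reaction databases from asymmetric catalysis for
entries whose reported stereochemical outcome is probably wrong. This
note describes the model, its assumptions, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## The screening problem

Curated databases of enantioselective reactions inherit human errors
from the primary literature and from transcription: the most damaging
is a *stereochemical misassignment*, where the reported major enantiomer
is in fact the minor one. On the %top scale (percentage of nucleophile
addition to the "top" prochiral face of the Michael acceptor; 50 =
racemic) such an error inverts the label to 100 − %top, i.e. it moves a
point from one edge of the range to the other. The premise of the
method is that facial selectivity is largely a systematic function of
catalyst and substrate structure, so a model trained on the bulk of the
data will predict an inverted entry near its *true* value and disagree
with the recorded label by a large margin — misassignments surface as
extreme residuals, repeatedly, across an ensemble of models.

This is a screening tool, not an oracle: a flag means "a majority of
independently trained models disagree strongly with this label", which
a chemist then adjudicates against the primary literature. Flags can
also be produced by genuinely unusual chemistry (e.g. s-cis/s-trans
conformer effects in acyclic enones, or ligands represented only once
or twice), so the output is a ranked short-list, never an automatic
correction.

## Reaction representation

Each reaction couples three component molecules — chiral ligand,
Michael-acceptor substrate, organoboron reagent — given as isomeric
SMILES. Each component is parsed, hydrogens left implicit, atoms
renumbered into the toolkit's canonical order (so any SMILES of the
same structure yields the same graph), and encoded one row per heavy
atom with six strictly one-hot groups, total width 24:

| group | slots | levels |
|---|---|---|
| element | 8 | B C N O F P S, other |
| heavy-atom degree | 5 | 0 1 2 3 4+ |
| hybridization | 4 | sp sp2 sp3, other |
| aromaticity | 2 | no / yes |
| ring membership | 2 | no / yes |
| CIP configuration | 3 | R / S / none |

Degree counts non-hydrogen neighbours only. CIP labels come from the
toolkit's stereo perception; centres it cannot assign encode as "none".
The exact split of the 24 columns is a schema object serialized with
every trained model, so alternative allocations can be restored without
touching code. Bonds are untyped and unweighted; the three component
graphs are merged as a disjoint union (no inter-component edges) and
the network's pooling stage mixes the components into one
reaction-level vector.

Axial chirality (e.g. binaphthyl-type bisphosphines) is not expressible
in atom-centred R/S slots; ligands whose chirality is purely axial have
no invertible stereocenter and are reported as such by the enantiomer
augmentation (below). This is a known representational limit.

## Enantiomer augmentation

For a prochiral substrate, the mirror-image catalyst produces the
mirror-image product. Each real record therefore spawns one virtual
record with every tetrahedral chiral tag of the ligand inverted and
label 100 − %top, exactly. Double-bond (E/Z) geometry is deliberately
left untouched: reflection preserves it, and inverting it would create
a diastereomer, not the enantiomer. Records whose ligand carries no
invertible tetrahedral descriptor are skipped and reported rather than
silently duplicated. Inversion is an involution: mirroring twice
returns the canonical form of the original SMILES.

## The regressor

A deliberately small graph network maps a reaction graph to a %top
prediction:

1. graph convolution 24 → 64, leaky-ReLU;
2. graph convolution 64 → 64, leaky-ReLU;
3. element-wise mean-pool and max-pool over all nodes, concatenated
   → 128;
4. dense 128 → 64, leaky-ReLU;
5. dense 64 → 1 (the %top prediction, unbounded — no output squashing).

The convolution is the symmetric-normalized neighbourhood average with
self-loops, Â = D^−1/2 (A+I) D^−1/2, applied as Â·H·W + b. This variant
was chosen as the standard member of its operator class; it is a
declared implementation choice, and the layers are small enough that
the forward and backward passes are written directly in NumPy/SciPy
(sparse Â per graph, block-diagonal assembly per batch). Everything is
float64, so training is bitwise reproducible from its seed.

Training: Adam (β₁ = 0.9, β₂ = 0.999) on a per-batch RMSE loss, batches
of 40 graphs reshuffled every epoch, weight update after every batch.
After each epoch the validation RMSE drives two schedules, both using
*strict* improvement over the best value seen so far:

- learning rate: start 0.01, ×0.7 after 5 epochs without improvement
  (counter resets on decay and on improvement), floored at 1e-8;
- early stopping: halt after 30 epochs without improvement.

The returned weights are those of the best-validation epoch, the
standard early-stopping semantics. `max_epochs` caps runaway runs at
1000 by default; the nested-CV studies in the test-suite and the
acceptance script use 60, a scaled-down study size at which the
synthetic rule is fully learned (held-out RMSE approaches the injected
noise level). Loss is per-batch RMSE as such (not MSE with a final
root); the leaky-ReLU negative slope is 0.01. Weight init is Glorot
uniform; biases start at zero; all randomness (init, shuffling) flows
from one integer seed.

## Nested cross-validation ensemble

The dataset is split into k = 10 near-equal folds by seeded uniform
assignment (fold sizes differ by at most one). Each fold serves as the
test set once; within each test fold, each of the remaining 9 folds
serves as validation once while the other 8 train the model. That gives
k(k−1) = 90 training processes and 9 independent test predictions per
reaction — the ensemble the outlier vote needs. Per-process seeds are
derived deterministically from (global seed, test fold, validation
fold), so any single process can be reproduced in isolation. A failed
process is recorded and its cell left missing; the sweep continues.

Folds are not stratified and enantiomeric twins are *not* co-assigned:
a virtual record may land in a different fold from its real twin, which
leaks ligand-level information across the test boundary. A
grouped-by-ligand fold option exists (off by default) for measuring
that effect. For the parity summary, each reaction's available test
predictions are averaged and RMSE/MAE/R² are computed over these
per-reaction means.

## Outlier criterion and vote

Within one training process, let e be the vector of absolute test-set
errors (candidate included). The default criterion flags reaction i
when

    e_i − mean(e) > 3 · SD(e),   SD population (ddof = 0).

The mean centering is essential to the method's logic: if a model is
uniformly poor, every error is large but none stands out, and nothing
is flagged. The uncentered literal form (e_i > 3·SD(e)) is retained as
a configuration option, as is sample SD. Two consequences worth knowing:

- the criterion is scale-free — multiplying all errors by c > 0 leaves
  the flag set unchanged;
- for a test set of n points the maximal z-score is √(n−1), so with
  n ≤ 10 the centered 3σ rule *cannot* fire. Test folds must be
  reasonably sized for the criterion to be meaningful.

Across the 9 processes of a reaction's test fold, flags are counted; a
reaction flagged in 5 or more of 9 processes (an absolute majority) is
reported as a suspected misassignment. The threshold stays absolute
when processes are missing, with a warning. The curation report ranks
flagged reactions by vote count, ties broken by reaction id, and
states the flagged fraction of the dataset — the measure of how much
manual re-checking the screen saves.

## The synthetic benchmark

Real reference datasets cannot ship with the package, so the generator
builds datasets with the same shape and a known ground truth. Ligands
are enantiomeric pairs of small one-stereocenter scaffolds
(C[C@H](a)(b) with varied substituents, so CIP labels are well defined
and mirror pairs are exact); substrates are split between cyclic enones
and deliberately ring-free acyclic enones (so cyclicity is expressed
purely in the ring features); reagents are substituted boronic acids.
The planted physics is

    %top = 50 + rule_strength · s · c + N(0, noise_sd), clipped to [0,100]

with s = ±1 the ligand's CIP configuration and c = ±1 the substrate's
cyclicity — a caricature of the empirical quadrant-model logic by which
ligand chirality (together with substrate class) sets the favoured
face. A seeded fraction of records is then inverted to 100 − %top and
returned as ground truth. Default study conditions: 400 reactions, 12
ligands, 10 substrates (half cyclic), 8 reagents, rule_strength 45,
noise_sd 5, flip_fraction 0.03, flips placed uniformly (an option
clusters them by ligand, mimicking laboratory-level systematic errors;
off by default).

What passing the benchmark shows: the full pipeline — featurization,
90 trainings, 3σ vote — recovers a large majority of planted inversions
while flagging almost no clean records, under conditions where the
selectivity rule is strong, the noise moderate, and the flips
independent. What it does not show: performance on real data, where the
"rule" is only approximately structural, noise is heteroscedastic
across laboratories, misassignments cluster by paper, axial chirality
is invisible to the representation, and conformer effects genuinely
invert outcomes for some acyclic substrates. Recovery degrades as
noise_sd grows toward rule_strength, which mirrors the real-data
observation that contradictory literature for acyclic acceptors limits
what the model can learn.

## Numerical and degenerate-input choices

- %top is stored on the 0–100 percentage scale throughout.
- Rows failing validation on load (unparseable SMILES, %top outside
  [0,100]) go to a machine-readable rejection report; loading aborts
  only if *no* valid rows remain. CSV floats are read with round-trip
  precision so save→load is exact.
- A zero-loss batch propagates zero gradients (the RMSE derivative is
  left at 0 rather than dividing by 0).
- Graphs with a single node pool to mean = max by construction.
- An isolated node's normalized adjacency degenerates to its self-loop.
- Non-finite losses raise immediately with epoch/batch context.
- `pct_top_from_er(0, 0)` and criterion evaluation on fewer than two
  errors are domain errors.

## Known limitations

- Axial chirality is not representable in atom-centred CIP slots
  (affects atropisomeric bisphosphine ligands); such ligands need a
  pre-mirrored SMILES entered manually for augmentation.
- No bond features, no 3D/conformer information: outcome differences
  driven by s-cis/s-trans conformer populations are invisible.
- The 3σ criterion needs adequately sized test folds (see the √(n−1)
  bound) and assumes misassignments are a small minority; a dataset
  where a third of the labels are wrong would poison the ensemble.
- Training processes run sequentially; they are independent and share
  nothing mutable, so a parallel executor is possible, but none is
  built in.
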