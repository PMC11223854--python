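# Methods

## The model

`aprnet` treats aggregation-prone region (APR) detection as a two-stage
problem: (i) binary classification of hexapeptides as amyloid-prone, and
(ii) lifting hexapeptide scores onto whole protein sequences.

**Hexapeptide classifier.** Each of the six residues is encoded by 36
numeric descriptors, so a window is a 6 × 36 matrix. The classifier is an
eight-layer network: a time-distributed dense projection (tanh, 36 → 64 per
residue), a bidirectional LSTM over the six residues returning per-step
states (2 × 32 = 64 wide), a second bidirectional LSTM whose two final
states are concatenated (2 × 48 = 96), two ReLU dense layers of 32 units
each followed by inverted dropout, and a linear unit with logistic
squashing. Declared layer widths are the *outputs* of each layer; a
bidirectional width is split evenly across the two directions. The
reduction from per-step states to a fixed vector uses the final state of
each direction (each direction having read the whole window); this wiring
choice is recorded in every saved model manifest. The assumption built into
this architecture is that aggregation propensity of a short peptide is a
(possibly order-sensitive) function of local residue chemistry — there is
no structural input.

**Ensemble.** Five networks, one per cross-validation fold, are combined by
arithmetic mean. The consensus score is therefore in [0, 1] and invariant
to member order; ensembles are fixed at five members (an explicit override
exists for tests and is logged).

**Whole-protein profiles.** A protein of length L yields L − 5 overlapping
hexapeptide windows (step 1). Residue i receives the plain mean of the
windows covering it; the first and last five residues are covered by fewer
than six windows and are averaged over their actual coverage — no padding,
since padding would invent window scores. APRs are maximal runs of at least
six consecutive residues with score ≥ threshold; above-threshold peaks
shorter than six residues are visible in the profile but never called.
User-facing coordinates are 1-based inclusive; internal arrays are 0-based
half-open.

## Training procedure

* Stratified 90/10 split: per class, round(0.9 × n) items to training
  (round-half-even), remainder to test.
* Stratified 5-fold plan on the training split; per-class fold sizes differ
  by at most one.
* Loss: binary cross-entropy (optionally inverse-frequency class-weighted;
  off by default since the method's native datasets are only moderately
  imbalanced). Optimizer: Adam at the configured learning rate. Gradients
  are hand-derived (backpropagation through time for the LSTMs) and checked
  against central finite differences in the test suite.
* Per epoch, AuROCC is computed on the training and validation fold. The
  "stop where training and validation ROC curves diverge" criterion is
  operationalized as patience early stopping: training halts after
  `patience` consecutive epochs without a ≥ `min_delta` validation
  improvement, and the weights of the best-validation epoch (first
  occurrence on ties) are retained. Defaults: patience 5, min_delta 0.001,
  max 200 epochs.
* After the five members are trained, the ensemble's Youden-J threshold is
  computed on the full training split and stored in the manifest as the
  default operating point.
* Determinism: every stochastic step (splits, folds, initialization, batch
  order, dropout masks) flows through seeded `numpy.random.Generator`s, so
  identical data + config + seed reproduce identical models on a single
  thread.

## Hyperparameters

| parameter | default | allowed | notes |
|---|---|---|---|
| bidirectional layers | 2 | 1–2 | last one returns final states |
| dense layers | 3 | 1–3 | includes the 1-unit output layer |
| dropout | 0.2 | {0, 0.2, 0.4, 0.6, 0.8} | dense block only, inactive at inference |
| layer widths | 64, 64, 96, 32, 32 | integers in [8, 512], even for biLSTM | see below |
| batch size | 32 | {16, 32} | |
| learning rate | 1e-3 | {1e-4, 1e-3, 1e-2, 1e-1} | Adam |

The configuration grids above define the hyperparameter search space; the
search tool enumerates a deterministic grid (one shared power-of-two width
per layer) or draws seeded random configurations, each evaluated by
cross-validated mean validation AuROCC, under an explicit budget. Note that
the default architecture's 96-wide layer is itself not a power of two, so
width *validation* only enforces the [8, 512] range and evenness — the
strict powers-of-two restriction applies to search-space generation, where
it keeps the grid small.

The default dropout (0.2), batch size (32) and learning rate (1e-3) are the
package's choices from the allowed grids: the mildest regularization that
still acts on the dense block, and the standard Adam setting for problems
of this size.

## The residue feature table

The 20 × 36 default table (`aprnet/data/aa_features_default.tsv`) is a
curated in-package descriptor set: counts of C/H/N/O/S atoms, total and
heavy atoms, side-chain heavy atoms, residue mass, volume, accessible
surface area, five hydrophobicity/hydrophilicity scales (Kyte–Doolittle,
Hopp–Woods, consensus, octanol, interface transfer), charge and pKa
quantities, polarity, refractivity, flexibility, bulkiness, helix/sheet/turn
propensities, hydrogen-bond donor/acceptor counts, several categorical
flags (aromatic, aliphatic, polar, charged, tiny, β-branched, helix
breaker) and rotatable-bond counts. Atomic compositions are computed
exactly from residue molecular formulas; scale values are standard
published constants rounded to their usual precision. Any table with the
same layout (header of feature names, first column the one-letter code, 20
rows) can be substituted via `load_feature_table`; trained models record a
content hash of their table and refuse to load against a different one.
Non-canonical residues (X, B, U, gaps) are rejected rather than imputed —
an imputation rule would silently distort profiles. An optional per-feature
z-scoring (fitted on the training split only) is available and off by
default.

## Evaluation harness

* Precision = TP/(TP+FP), Recall = TP/(TP+FN), Specificity = TN/(FP+TN).
  Zero-denominator cases return NaN (flagged, logged) and are excluded from
  macro averages — substituting 0 or 1 would bias averages over proteins.
* ROC curves use one point per distinct score (ties share a threshold) and
  trapezoidal area; this equals the pairwise-ordering statistic with ties
  counted 0.5, which the tests verify to 1e-12. PR area uses
  non-interpolated step summation (average precision); trapezoidal PR
  interpolation is optimistic and is not used. Both curves are computed
  through scikit-learn behind this module's interface.
* Youden's J = recall + specificity − 1 is maximized over the ROC's
  thresholds; ties break toward the smallest finite threshold. Scores equal
  to the threshold classify as positive.
* SOV uses the refined (1999) segment-overlap definition: per overlapping
  reference/prediction segment pair, (minov + δ)/maxov weighted by
  reference length, with δ capped by minov, maxov − minov and half of
  either segment length; unmatched reference segments contribute only to
  the normalizer. Scores are reported on 0–100 separately for APR and
  non-APR segments. A protein with no segment of the requested class gives
  NaN for that class. The earlier 1994 normalization is not implemented;
  the refined variant is the one in contemporary use.
* Whole-protein ground truth from interval annotations is the union of
  intervals (overlapping or abutting annotations merge). Per-protein
  metrics are macro-averaged.

## Synthetic data

`gen_hexapeptides` draws positives residue-by-residue from a composition
biased toward hydrophobic/β-prone residues (I, V, L, F, Y, M, W) and
negatives from a charged/P/G/S-rich composition; label noise flips labels
independently at the requested rate. The rule is compositional rather than
motif-exact so a classifier must generalize, and it is recoverable by
construction: mean Kyte–Doolittle hydropathy alone reaches AuROCC ≥ 0.9 at
zero noise (the tests and acceptance script confirm ≈ 0.99). Default size
500 with 30% positives, echoing the scale and imbalance of curated
hexapeptide collections. `gen_annotated_proteins` embeds 6–20-residue
positive-composition segments into negative-composition backgrounds
(never longer than 50 residues, never touching the terminal six positions,
at least six residues apart) and records them as the true APRs.

What passing on this synthetic world shows: the encoding, training loop,
early stopping, ensembling, windowing, thresholding and all evaluation
mathematics are correct, and the full pipeline can learn a known separable
compositional signal end-to-end. What it does not show: performance on real
amyloid data, where labels are noisy, the signal is weaker and
position-specific (gatekeeper residues, register effects), and long
low-complexity APRs exist. Real-data performance requires retraining on a
curated export (see README).

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at n = 500
hexapeptides, ≤ 30 epochs and ≤ 8 annotated proteins of length ≤ 200 —
sizes at which the synthetic signal saturates and results are stable across
seeds. Oracle comparisons (pairwise AUC, exhaustive Youden search, coverage
enumeration, the independent SOV implementation) use tolerance 1e-12;
training-dependent checks use the margins stated in the tests (e.g.
held-out AuROCC ≥ 0.95 across three seeds at zero noise). Weight
initialization is Glorot-uniform with forget-gate biases at 1; ensemble
member seeds are derived deterministically from the run seed.

## Known limitations

* Sequence-only: no solvent accessibility, transmembrane context or
  structure; buried hydrophobic stretches will score high even when they
  are never exposed.
* Hexapeptide-centred: APRs much longer than the window (low-complexity or
  prion-like domains) are detected only through their short cores.
* The NumPy training loop is single-threaded and CPU-bound; it is sized for
  datasets of 10²–10⁴ hexapeptides, not for large-scale pretraining.
* The shipped feature table is a curated default, not the only reasonable
  choice; conclusions about feature importance should not be drawn from it.
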