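# aprnet

Aggregation-prone region (APR) prediction from protein sequence.

Protein aggregation — and its most ordered form, amyloid formation — is a
central failure mode in recombinant protein production and a hallmark of
several diseases. The regions that nucleate aggregation are short, mostly
hydrophobic, β-prone stretches; finding them from sequence alone lets
protein engineers target solubilizing mutations. `aprnet` implements a
hexapeptide-centred predictor of such regions: an ensemble of five small
bidirectional-LSTM networks classifies six-residue peptides as
amyloid-prone, and a sliding-window procedure lifts those scores to a
per-residue aggregation profile of a whole protein, from which APRs are
called. The package also contains the complete training machinery
(stratified splitting, 5-fold cross-validation, early stopping on the
train/validation ROC divergence, hyperparameter search) and the evaluation
harness (confusion-matrix metrics, AuROCC/AuPRC, Youden-J thresholding,
Segment OVerlap scores), plus synthetic data generators so the entire
pipeline is testable offline.

## Method

Each residue is encoded by 36 numeric descriptors (atomic composition and
standard physicochemical scales; the table is pluggable), so a hexapeptide
is a 6 × 36 matrix. A network maps this window to a score in [0, 1]
through eight layers:

    input (36·6) → time-distributed dense (64·6)
                 → biLSTM (64·6, sequences) → biLSTM (→ 96, final states)
                 → dense+dropout (96 → 32) → dense+dropout (32 → 32)
                 → dense (32 → 1, sigmoid)

Training uses binary cross-entropy with Adam, monitored each epoch by the
area under the ROC curve (AuROCC) on the training and held-out fold; the
retained weights are those of the best-validation epoch (patience early
stopping). Five folds give five networks; the deployed predictor is their
arithmetic-mean consensus.

For a protein of length L, the L − 5 overlapping hexapeptide windows are
scored and each residue receives the mean of the windows covering it
(termini average over their reduced coverage). Residue stretches of at
least **six** consecutive positions at or above the threshold — by default
the Youden-J point (argmax of recall + specificity − 1) computed on the
training data — are reported as APRs; shorter peaks are not.

The networks are implemented directly on NumPy with hand-derived
backpropagation through time (verified against numerical gradients in the
test suite); no deep-learning framework is required.

## Worked example

```python
from aprnet import AggregationNet, synthetic

data = synthetic.gen_hexapeptides(synthetic.SyntheticSpec(n_hexapeptides=500, seed=1))
res = AggregationNet(data).fit(seed=1, max_epochs=30)
print(res.summary())
```

```
                Aggregation-prone region predictor
==================================================================
Ensemble members:                                                5
Architecture layers:                                             8
Layer widths:                                       64x64x96x32x32
Dropout / batch / lr:                             0.2 / 32 / 0.001
Seed:                                                            1
------------------------------------------------------------------
fold 0: stopped at epoch  11   validation AuROCC 0.9953
fold 1: stopped at epoch   3   validation AuROCC 1.0000
fold 2: stopped at epoch   2   validation AuROCC 1.0000
fold 3: stopped at epoch   6   validation AuROCC 1.0000
fold 4: stopped at epoch  12   validation AuROCC 0.9982
------------------------------------------------------------------
Youden-J threshold (train):                                 0.4476
Held-out test AuROCC:                                       1.0000
Held-out test AuPRC:                                        1.0000
==================================================================
```

The summary reports, per cross-validation fold, the early-stopping epoch
and the fold's validation AuROCC, then the Youden-J operating threshold
and the ranking quality on the 10% of hexapeptides never seen in training.
Profiling a protein and calling APRs:

```python
prot = synthetic.gen_annotated_proteins(1, length_range=(90, 90), seed=2)[0]
prof = res.profile(prot.sequence, prot.id)
for c in res.aprs(prof):
    print(f"APR {c.start}-{c.end}  mean {c.mean_score:.3f}  max {c.max_score:.3f}")
```

```
APR 32-41  mean 0.710  max 0.834
APR 60-71  mean 0.692  max 0.830
```

which recovers the two embedded aggregation-prone segments of that
synthetic protein (true intervals 32–40 and 58–69). `res.evaluate(...)`
scores such predictions against annotations (per-protein and
macro-averaged AuROCC, AuPRC, SOV-APR, SOV-non-APR), `res.plot_profile`
draws the profile, and `res.save / AggregationNetResults.load` persist the
ensemble with a full manifest.

The same workflow is available from the shell:

```bash
aprnet synth --n 500 --proteins 5 --seed 1 --out data/
aprnet train --dataset data/hexapeptides.csv --seed 1 --out model/
aprnet predict --model model/ --fasta data/proteins.fasta --out predictions/
aprnet evaluate --model model/ --annotations data/proteins.json --out eval/
aprnet search --dataset data/hexapeptides.csv --budget 5 --out ranked.json
```

To retrain on real data, export a curated hexapeptide collection (e.g. a
WaltzDB export) to the `sequence,label` CSV dialect and run `aprnet train`
on it; no such download is performed by this repository.

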