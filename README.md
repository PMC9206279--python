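# gquadfold

G-quadruplex (G4) identification, topology annotation, and machine-learned
folding prediction for DNA and RNA sequences.

G4s are four-stranded secondary structures formed by guanine-rich nucleic
acids: four G-runs (stems) donate guanines to stacked, Hoogsteen-bonded
G-quartets, connected by short loops. G4 motifs are abundant in telomeres
and regulatory regions, but a motif is only biologically relevant if it
actually folds — and many canonical motifs instead form Watson–Crick
hairpins, especially when cytosines sit nearby. `gquadfold` addresses both
halves of the problem: it finds and describes G4 motifs, and it predicts —
from sequence-intrinsic features alone, no flanking context or experimental
data required — whether each motif folds into a quadruplex and how stable
that fold is.

## What it computes

**1. Topology under a refined equal-stem definition.** The canonical motif
`(G₃₊N₁₋₇)₃₊G₃₊` can match spans whose G-runs are unequal — e.g.
`GGGtttttttGGGGGtttttttGGGtttGGG`, whose second run carries five guanines.
Since every stem of a quadruplex must contribute the same number of
guanines, the refined parse `(G₁₋₈L₁₋₁₂)₃₋₁₁G₁₋₈` forces an equal quartet
count *q* per stem (here *q* = 3, set by the shortest run) and pushes the
surplus guanines into the adjacent loops, reporting the loop-length extrema
over all admissible placements (here 3–9 nt; the 9 exceeds the canonical
7-nt bound, which is exactly why the refined definition is needed). The
parser maximizes *q*, then prefers fewer stems, then the leftmost window.

**2. Folding state and free energy.** Each motif is folded by a
quadruplex-aware minimum-free-energy engine (ViennaRNA with G-quadruplex
terms; DNA is folded as RNA after T→U). A motif is *folded* iff the MFE
structure contains quadruplex pairing (`+` in dot-plus notation); a
hairpin-forming motif counts as unfolded even at low energy. The MFE in
kcal/mol is the stability label.

**3. Learned prediction.** Gradient-boosted trees (XGBoost) are trained on
engine-labeled corpora: a classifier for the folding state and a regressor
for the folding energy, using ten sequence-intrinsic features (quartet
count, loop count, loop min/max, query and motif lengths, G/C mono- and
GG/CC dinucleotide frequencies). Evaluation is stratified/shuffled 5-fold
cross-validation with accuracy, balanced accuracy, precision, recall, F1,
AUROC (classification) and RMSE, R², explained variance, MAE (regression).

## Worked example

```bash
printf ">example\nGGGtttttttGGGGGtttttttGGGtttGGG\n" > demo.fa
gquadfold annotate --fasta demo.fa --out demo_topo.tsv
```

```
query_id  q  n_loops  loop_min  loop_max  motif_start  motif_end
example   3  3        3         9         0            31
```

The second G-run's two surplus guanines join the flanking loops: depending
on placement the first loop grows to 7–9 nt and the second shrinks
accordingly, so the loop extrema are 3 and 9 while every stem contributes
exactly three guanines.

A full pipeline on a synthetic corpus (sequences with controllable stem
counts, loop lengths, loop C-content, and non-G4 negatives):

```bash
gquadfold simulate --n 2000 --seed 11 --negative-fraction 0.35 \
    --out corpus.fa --truth truth.tsv
gquadfold label --fasta corpus.fa --out table.tsv
gquadfold train --table table.tsv --task classify --seed 1 --out clf.joblib
gquadfold train --table table.tsv --task regress  --seed 1 --out reg.joblib
gquadfold predict --fasta demo.fa --classifier clf.joblib \
    --regressor reg.joblib --mode annotate --out demo_pred.tsv
```

which prints the cross-validation means

```
xgboost classify CV means: {'accuracy': 0.9343, 'balanced_accuracy': 0.9247,
 'precision': 0.943, 'recall': 0.9567, 'f1': 0.9498, 'auroc': 0.9803}
xgboost regress CV means: {'rmse': 1.7571, 'r2': 0.9876,
 'explained_variance': 0.9876, 'mae': 1.0306}
```

and the three-layer prediction for the example record:

```
query_id  start  end  strand  q  n_loops  loop_min  loop_max  fold_probability  fold_call  predicted_energy
example   0      31   +       3  3        3         9         0.9915            True       -21.47
```

i.e. the motif is predicted to fold into a quadruplex (probability 0.99 at
the default 0.5 threshold; `--threshold` trades precision against recall)
with an estimated folding energy of −21.5 kcal/mol.

## Library surface

```python
from gquadfold import (scan_canonical, parse_topology, fold, build_training_table,
                       train_classifier, train_regressor, predict,
                       CorpusSpec, generate_corpus)
```

`scan_canonical` finds canonical motifs on both strands (minus-strand hits
are reported as reverse complements with forward coordinates);
`parse_topology` applies the refined equal-stem parse to any sequence;
`fold` labels a sequence with structure/energy/state; `generate_corpus`
emits seeded synthetic corpora with truth tables; `train_*` return
persistable model bundles whose predictions refuse mismatched feature
schemas.

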