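# Methods

## The refined equal-stem topology parse

A G-quadruplex motif is modeled as `k` stems (4 ≤ k ≤ 12) of exactly `q`
guanines each (1 ≤ q ≤ 8), joined by loops of 1–12 nt. Input sequences are
first decomposed into maximal G-runs. The parser then:

1. enumerates contiguous windows of `k` consecutive runs;
2. sets `q = min(8, shortest run in the window)` — stems must be equal, so
   the shortest run caps the quartet count;
3. declares a window admissible if some placement of the stems inside their
   runs keeps every loop within 1–12 nt. Terminal stems are anchored at the
   window's outermost run edges (so terminal surplus guanines fall into
   loops rather than being silently discarded); internal stems may sit at
   any offset, with a run's surplus guanines joining the adjacent loops;
4. selects the admissible window with maximal `q`, breaking ties toward
   fewer stems and then the leftmost window;
5. reports the minimum and maximum loop length over *all* admissible
   placements of the winning window — the quantity of interest when surplus
   guanines can slide between neighbouring loops.

Admissibility and loop extrema are computed by forward/backward
reachability over per-stem offset domains; because the loop constraints
form a chain, a locally consistent offset pair extends to a full admissible
placement, making the arc-consistency pass exact. The test suite checks
this against an independent brute-force oracle that enumerates every
placement by depth-first search.

Two structural choices were genuinely open and are fixed here: a single
maximal G-run is never split into two stems (a loop consisting solely of
guanines is not a meaningful loop), and windows never skip a run (skipping
would silently bury a whole G-run of ≥ q guanines inside a loop). Both
choices are shared by the parser and the oracle.

Canonical scanning uses the greedy regular expression
`(G{3,}N{1,7}){3,}G{3,}` left-to-right without overlap, on the forward
strand and on the reverse complement; minus-strand hits are reported in
forward coordinates with the reverse-complement motif sequence. `N` is
accepted in loops, never in stems.

## Folding labels

The folding engine is an injectable contract (`fold_structure(seq) ->
(dot-plus string, energy)`). The production engine is ViennaRNA with
G-quadruplex terms enabled; DNA is mapped T→U and folded with RNA energy
parameters, a documented approximation that reconstructs DNA secondary
structure with acceptable accuracy. A motif is *folded* iff its MFE
structure contains `+` (quadruplex pairing); hairpins and unstructured
outputs are *unfolded*, whatever their energy. Unstructured sequences get
energy 0.0.

Engine-adapter details that matter for reproducibility:

- ViennaRNA ≥ 2.7 marks the 3′-most quadruplex position `~`; the adapter
  normalizes it to `+` so the structure alphabet is exactly `. ( ) +`.
- Quadruplex terms are enabled only when the sequence contains at least
  four G-runs of ≥ 2 guanines — otherwise no quadruplex candidate exists,
  the MFE result is identical with the terms off, and ViennaRNA's
  quadruplex scan (which is extremely slow on short sequences through the
  python bindings) is skipped.
- A deterministic rule-based mock engine mirrors the contract for
  environments without ViennaRNA: an admissible parse with q ≥ 2 and low
  cytosine content folds; G/C-rich sequences form a caricature hairpin;
  everything else is unstructured. It is a testing device, not a
  thermodynamic model.

Energies of folded and unfolded motifs alike enter the regression label,
so the regressor learns the full MFE landscape rather than the folded
subset only.

## Features and models

26 features describe a (query sequence, motif) pair: quartet count, loop
count, loop min/max, motif length, query length, 4 mononucleotide and 16
overlapping dinucleotide frequencies. Frequencies are proportions —
counts/L for monomers and counts/(L−1) for dimers, with N-containing
windows excluded from both numerator and denominator. Composition is
computed over the full query sequence, not the motif alone, because
cytosines *around* the motif compete for stem guanines and carry signal.
The default model input is the 10-feature subset: topology (4), lengths
(2), G/C monomer and GG/CC dimer frequencies.

The classifier (folding state) and regressor (folding energy, kcal/mol)
default to XGBoost with 200/300 trees, depth 6, learning rate 0.3, run
single-threaded for bit-reproducibility; seven further classifier families
and two regressor families are available for benchmarking. Evaluation is
5-fold cross-validation — stratified with shuffling for classification,
shuffled for regression — reporting per-fold and mean±sd metrics plus
ROC/PR curve points, followed by a refit on all rows. Random-search tuning
evaluates a seeded draw from a documented search space on the same folds
and always includes the default configuration, so the tuned model is never
worse than the defaults by the selection metric (mean F1, or mean RMSE for
regression). Tree-model importance is exported under the unambiguous names
`split_count` and `total_squared_improvement`; the `gain`/`weight` aliases
follow the convention in which *gain* counts splits and *weight* measures
squared improvement (transposed relative to the xgboost API's naming, which
is why both raw names are primary).

Class imbalance is handled by reporting F1 and balanced accuracy, not by
reweighting. The default decision threshold 0.5 is stored in the model
bundle and overridable at prediction time.

## Synthetic corpus

The generator emits motifs stem-by-stem with seeded, controllable
distributions. Defaults approximate a genome-scan corpus under the refined
definition: quartet counts centered on 3 (weights 0.05/0.15/0.50/0.18/0.08/
0.04 for q = 1…6), 4–8 G-runs (mostly 4), loop lengths dominated by 1–7 nt
with a tail to 12, 10-nt flanks, and with probability 0.15 one internal run
carrying 1–2 surplus guanines so the equal-stem machinery is exercised.
Negatives (default fraction 0.3) come as C-rich-loop motifs (quadruplex
shape, folding suppressed by G–C pairing), mononucleotide-exact shuffles of
positives, or random low-G background. Folding labels always come from the
engine, never from the generator.

Loops and flanks are guanine-free by construction. This is what makes the
emitted truth table analytically exact — the parser provably selects the
leftmost four-run window, and the surplus-adjusted loop extrema follow in
closed form — and it is also the generator's main departure from real
genomic sequence, where loops do contain guanines and motifs overlap.
Consequently, passing pipeline tests demonstrate that the machinery learns
engine labels from the stated features in a realistic composition range;
they do not certify genome-scale performance on natural sequence context.

## Problem sizes and numerical choices

The scaled-down pipeline used in the acceptance tests generates 20,000
records (seed fixed), labels them with the ViennaRNA engine, and
cross-validates both models; parser–oracle equivalence uses 1,000 random
sequences of length 20–80 at G-fraction 0.3–0.6. These sizes were chosen to
exercise every code path at desk scale while keeping a full test run under
a minute; corpus size mainly tightens the CV standard deviations.

Ties in feature ranking are broken by schema order, so constant columns
(zero score) sort deterministically. Model bundles embed the feature
schema, trained hyperparameters, decision threshold, CV report, and a
training-table fingerprint; prediction on a table missing schema columns
fails loudly with the missing names. All stochastic components (corpus
generation, fold shuffling, search draws) consume explicit integer seeds.

## Known limitations

- Bulged or mismatched stems, multimeric/inter-strand quadruplexes, and
  composition scoring of the G4Hunter type are out of scope; bi/tetra-
  molecular structures can only be approximated via the poly-T joining
  helper (default 3-T linkers, overridable per junction).
- The folding label inherits every limitation of the MFE engine: RNA
  parameters applied to DNA, no cation-concentration or temperature
  modeling, a single MFE structure rather than an ensemble.
- Predicted energies are only as good as the engine labels the models were
  trained on; on sequences unlike the training corpus (very long loops,
  G-rich flanks) the models extrapolate.
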