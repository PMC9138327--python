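# Methods

## Problem and model

`dtifusion` treats drug–target interaction prediction as binary
classification of (SMILES string, amino-acid sequence) pairs. The
model's premise is that useful signal lives in *local* sequence
patterns — short residue motifs on the protein side, substructures on
the drug side — and that several cheap complementary views of the same
pair, fused late by concatenation, are more robust than one deep
encoder. The four views are a protein CNN, a protein transformer
encoder, a drug (character) CNN and a dense network over the hashed
circular fingerprint; each reduces to a fixed-width vector, and a dense
head with one sigmoid unit maps the concatenation to an interaction
probability.

Implicit assumptions: interactions are determined by sequence content
alone (no structure, no concentration); the label is binary; and the
training distribution of drugs/proteins resembles the evaluation
distribution (the stratified split shares both entities across
partitions — this is *not* a cold-start protocol).

## Vocabularies

The protein dictionary contains all 26 uppercase letters plus every
2-mer and 3-mer that passes a frequency screen: a candidate is kept if
at least one corpus sequence contains it at least
`min_per_sequence_count` (default 7) times, counting overlapping
occurrences. The per-sequence reading of the rule is the default
because high multiplicity within one sequence indicates a repeated,
possibly structural element; a corpus-total mode is available
(`ScreenConfig(corpus_total=True)`) and its effect on dictionary size is
reported by the acceptance checks when a real corpus is supplied.
Single letters are never screened: greedy segmentation leaves
single-residue residuals, so the letters must always be present — this
also guarantees tokenization succeeds for any uppercase input. Order 4
is excluded deliberately: ~475 k candidates would inflate the
dictionary while 3-mers already achieve roughly 2× compression.

The drug dictionary is the distinct characters of the SMILES corpus,
sorted by code point, taken verbatim (case-sensitive, so aromatic
lowercase atoms are distinct tokens). By default it is fitted on all
three partitions — the deployment-faithful reference protocol, which
leaks only the evaluation *alphabet*, not labels — with a `train_only`
option for a leakage-free variant. One extra id beyond the dictionary
is reserved for characters never seen at fit time; index 0 is padding
everywhere.

## Encoding

Protein segmentation is greedy longest-match left-to-right:
deterministic, O(n), exactly invertible. Truncation keeps the sequence
prefix (the N-terminus); padding is right-sided with id 0. Input
lengths default to m = 800 tokens (proteins) and v = 100 (drugs) for
real-scale data; both are plain config fields. Fingerprints are
radius-2 hashed circular fingerprints folded to 2048 bits via RDKit;
records whose SMILES cannot be parsed are dropped by the data pipeline
(with the removal count reported) rather than imputed.

## Network details

* Embedding widths u = 20 (protein) and j = 10 (drug); Glorot-normal
  initialization throughout; separate embedding tables per channel
  (a `share_protein_embeddings` switch exists but independence is the
  default, which keeps single-channel ablations self-contained).
* CNN channels: 1-D convolutions of kernel sizes {4, 8, 12} × 64
  filters (protein) and {2, 4, 6} × 32 filters (drug), ReLU, global max
  pooling. Kernel sizes and filter counts are configurable; the
  defaults span short and long motifs at desk scale.
* Transformer channel: d_model = 20 (matching u, since the width is
  otherwise unconstrained), 4 encoder blocks with 5 heads (d_k = 4),
  position-wise feed-forward of width 80, sinusoidal positional
  encodings, post-norm residual blocks (pre-norm available via
  `norm_style="pre"`), global max pooling over positions.
* Padding discipline: pad embeddings are zeroed, pad keys receive a
  −10⁹ logit bias in attention, and pooling masks out windows/positions
  that touch no real token. Consequently outputs are invariant to extra
  padding, which the implementation exploits by trimming every batch to
  its longest real sequence (exact, large speedup).
* Whole-dimension ("spatial") dropout on embeddings, training only,
  default rate 0.1.
* Fingerprint channel: one dense ReLU layer of 128 units; fusion head:
  one dense ReLU layer of 128 units, then the sigmoid output unit.

## Training and evaluation

Loss is mean binary cross-entropy with probabilities clipped to
[1e-7, 1 − 1e-7], plus λ Σ w² over weight matrices (biases and
layer-norm parameters excluded), λ = 1e-5 by default. Optimization is
Adam (lr 1e-3), batch size 64, up to 50 epochs with early stopping after
10 epochs without validation-AUC improvement; the best-AUC epoch's
weights are returned. These optimizer values are conventional defaults
for networks of this size and are all configurable. Mini-batches are
drawn by a jittered length sort (similar-length proteins batched
together, batch order shuffled): with per-batch length trimming this
keeps attention cost near the true sequence lengths without
de-randomizing the gradient sequence.

Determinism: every random draw (init, shuffling, dropout) flows from
explicit seeds, and with single-threaded BLAS two runs with equal seeds
produce identical histories; across BLAS configurations reproducibility
is at the metric level. Computation is float32 by default; a float64
context (`autograd.use_dtype`) is used where tests compare against
finite differences or 1e-12-level oracles.

Evaluation constructs the ROC and PR curves over the threshold list
"distinct observed scores, descending, plus a sentinel above the
maximum", predicting positive at score ≥ t. Areas are trapezoidal (the
ROC area then equals the Mann–Whitney rank statistic exactly). The
operating threshold maximizes Youden's J = TPR − FPR with ties broken
toward the larger threshold (fewer positive calls); with no ranking
signal this degenerates to the sentinel. Precision at zero predicted
positives is defined as 1.0 (the usual PR-curve endpoint); F1 is 0 when
precision + recall = 0, and the degenerate case is logged. The ablation
harness retrains five configurations — each single channel within its
entity with the other entity intact, plus the full model — and keeps
raw test scores per row so every metric is recomputable.

## Dataset pipeline conventions

Duplicates are exact (smiles, sequence, label) string matches; a pair
carrying both labels is kept as two records and logged. Balancing keeps
all positives and uniformly subsamples negatives without replacement.
The stratified split assigns, per label class of size n,
`round(0.7·n)` to train, `floor(0.15·n)` to validation and the
remainder to test — with two classes of 6 571 this yields
9 200 / 1 970 / 1 972 and the three partitions always partition the
input exactly. Training subsampling keeps `round(fraction·n)` per class
(so 50 % of 9 200 is 4 600 and 30 % is 2 760) and never touches
validation/test. A leakage audit counts (smiles, sequence) pairs shared
between partitions; it is zero by construction for fresh splits.

## Synthetic benchmark

The generator emulates the *shape* of a curated binding benchmark:
uniform-random proteins of 50–100 residues over the 20 standard amino
acids, drugs assembled from 1–4 concatenation-safe SMILES fragments
(always parseable, so the fingerprint filter removes nothing), balanced
labels. Ground truth is a planted conjunction: interaction iff the
protein carries a 5-residue motif (default `WCNDH`, essentially absent
by chance) AND the drug contains the pyridine fragment `c1ccncc1`;
optional independent label flips add noise. Defaults are 200 proteins ×
300 drugs and 1 000 + 1 000 pairs — sized so a full training run takes
about a minute on one CPU.

What passing the end-to-end tests shows: the encoders, network,
optimizer and selection logic can jointly recover a clean conjunctive
sequence/substructure rule (Bayes AUC 1.0) at desk scale. What it does
not show: performance on real binding data, whose motifs are degenerate
and context-dependent, whose chemistry is vastly more diverse, whose
labels are noisy, and whose sequences are several times longer. Real
protein inputs also exercise the k-mer screening far more (random
synthetic sequences rarely admit any 2/3-mer at threshold 7, so their
dictionary stays near the 26 letters).

## Numerical choices and degenerate inputs

Softmax subtracts the row max before exponentiation; the sigmoid is
evaluated branch-wise to avoid overflow; BCE clips probabilities before
the logs. Max pooling splits gradients evenly across exact ties.
Attention masking uses a −10⁹ additive bias fused into the softmax.
Non-finite training loss raises immediately with the epoch named.
Empty corpora, single-class label vectors, zero-positive PR inputs,
out-of-range fractions and malformed vocabulary files raise typed
errors rather than propagating garbage.

## Known limitations

* Trained networks here are desk-scale demonstrations; the default
  m = 800 / v = 100 configuration is untested against real BindingDB-
  scale data within this repository (no download is performed).
* The transformer pooling choice (masked global max) and post-norm
  block order are reasonable conventions, not validated against
  alternatives.
* The rounding conventions of the split/subsample are fixed design
  choices; other roundings of the same ratios produce off-by-a-few row
  counts.
* The autodiff engine implements exactly the operations this model
  needs; it is not a general-purpose framework (no higher-order
  gradients, no GPU).
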