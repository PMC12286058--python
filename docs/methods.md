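# Methods

## Feature model

A transcript is an RNA string S = S₁…Sₙ over {A, C, G, U}; input FASTA
in the DNA alphabet is canonicalized (uppercase, T→U) and ambiguity
symbols (N, R, …) are preserved but invalidate every window that
contains them. The exact q-mer profile assigns to each of the 4^q
q-mers (indexed lexicographically, A<C<G<U) its count among the valid
windows of S. The (q, k)-mismatch profile assigns to q-mer Qᵢ the count
of valid windows within Hamming distance ≤ k of Qᵢ; "at most k"
includes the exact match, so the k = 0 profile is bit-identical to the
exact profile and counts are pointwise non-decreasing in k. For an
all-ACGU sequence the mismatch counts sum to
(windows) × B(q, k), with B(q, k) = Σ_{i≤k} C(q, i)·3ⁱ the Hamming-ball
size — both identities are enforced as property tests.

Both profile kinds are divided by the same denominator, the sequence's
exact valid-window count. The denominator is per sequence, not
corpus-wide: it keeps each exact profile a probability vector and each
mismatch profile on the scale of its ball size regardless of corpus
composition. Skipped (ambiguous) windows are excluded from the
denominator rather than imputed.

The production computation scatters each distinct window's count into
that window's Hamming ball (cost O(distinct windows × B(q, k)), with
balls memoized per q-mer); an independent naive implementation computes
the full feature × window Hamming-distance matrix and thresholds it.
The two must agree bit-exactly, and the test suite sweeps them over 200
random sequences for q ∈ {3, 4}, k ∈ {0, 1, 2}. The convention
k ≤ ⌊q/2⌋ (at least half the positions must match) is enforced as a
validation error with an explicit override, which the k = 2, q = 3 leg
of that sweep uses.

## Dataset construction

CN-RCI (log2 cytoplasmic/nuclear FPKM ratio) tables are joined to
transcripts by gene accession with version suffixes stripped. Rows with
missing CN-RCI are dropped, and when a biotype column is present only
non-coding rows are kept. Per gene, the longest transcript with length
in [200, 5000] nt is retained — bounds inclusive, since an lncRNA is
≥ 200 nt by definition; ties break to the lexicographically smallest
transcript id for determinism. Labels use a single threshold (default
0; the boundary belongs to the cytoplasmic class) to avoid the middle
exclusion problem, where discarding genes between two thresholds
inflates apparent accuracy. The train/test split is performed directly
on genes (4:1 by default), which guarantees the no-leakage property —
no gene on both sides — with less machinery than splitting transcripts
and reducing afterwards. A gene annotated in several cell lines
contributes one labeled row to each cell line's matrix over the same
transcript.

## Models

* **Autoencoder** — encoder: dense 256 and 128 units, each followed by
  batch normalization and ReLU, then 30% dropout and a linear latent
  layer (512 features by default; the latent width is a parameter, and
  32–512 are sensible values). Decoder mirrors the encoder (128, 256)
  and ends in a sigmoid, so reconstruction is trained with binary
  cross-entropy on inputs scaled into [0, 1] (normalized exact profiles
  already are; mismatch profiles are rescaled by their maximum
  defensively). Adam (lr 1e-3), batch 32, up to 100 epochs with early
  stopping (patience 10) on a 10% validation split. The loss is not
  stated by the architecture alone; BCE is implied by the sigmoid
  output and binary-like data. The autoencoder is always fitted on the
  training partition only and applied to the test partition.
* **1D-CNN** — the profile is read as a length-D single-channel signal
  (D = 4096 raw or 512 latent): conv 128 filters, kernel 3, He-normal
  init, ReLU; maxpool 3; conv 256 filters, kernel 3; maxpool 3;
  flatten; dense 256 + ReLU + 30% dropout; single sigmoid unit.
  Convolutions are unpadded ("valid"); the stated pooling arithmetic is
  consistent with either choice and valid is the simpler one.
* **MLP** — hidden layers 128/64/32 with ReLU, sigmoid output.
* **Random Forest** — scikit-learn, 100 trees, library defaults
  otherwise; the score is the positive-class vote fraction.

Neural training defaults (Adam 1e-3, BCE, batch 32, 50 epochs for the
classifiers) are conventional choices exposed as arguments. The
decision threshold on every score is 0.5. All neural components run on
the package's own numpy backend, which exists to keep the models
dependency-light and bit-deterministic under a fixed seed on a single
CPU.

## Imbalance and evaluation protocol

SMOTE balances the classes by interpolating each synthetic minority row
between a random minority row and one of its k = 5 nearest minority
neighbours (k is reduced with a warning when the minority class is
tiny). The alternative `class-weight` strategy weights samples inversely
to class frequency; `none` disables both. Cross-validation is
stratified 5-fold repeated twice with independent shufflings derived
from the master seed, and SMOTE is applied inside each training fold
only — the held-out fold never contains synthetic rows. Whether the
original protocol nested oversampling inside the folds is not
documented; nesting is the leakage-safe reading and is what the row
bookkeeping test asserts.

Metrics are computed from the confusion counts: OA, precision, recall
(= sensitivity), specificity, F1, and MCC with the standard denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); ROC-AUC comes from the continuous
scores. Ratios with a zero denominator are reported as 0 together with
a degeneracy flag, so fold aggregation never propagates NaN.

The cross-cell-line analysis trains one model per cell line on that
line's training genes and evaluates on every line's test genes from the
same gene-grouped split, reporting the accuracy matrix and the number
of rows whose diagonal is not the row maximum. Cell-line similarity is
additionally summarized by pairwise Pearson correlation of per-gene
CN-RCI over pairwise-complete genes (pairs sharing < 2 genes are
missing, not zero).

## Switching genes

For each gene, per-cell-line labels are thresholded from CN-RCI; C and
N count cytoplasmic and nuclear cell lines. A switching gene satisfies
C > 1, N > 1 and |C − N| ≤ 1 — observed in both compartments at least
twice, with near-balanced counts. The third condition is stated
incompletely in the source material ("≤ 1" with the quantity elided);
|C − N| ≤ 1 is the reading consistent with the census table's C−N
column and is recorded here as an interpretation. The H1.hESC cell
line, an outlier with low correlation to the other lines, is excluded
by default (overridable).

## Synthetic fixtures

The sequence generator emits uniform-random RNA backbones (default 400
genes, 200–500 nt — inside the lncRNA length window, short enough that
planted 6-mers dominate the background) and plants class-discriminative
6-mer motifs: by default three motifs per class and eight copies per
sequence (about one element per 50 nt, the density of a strongly
repeated protein-binding site), at insertion rate 1.0. Each copy may be
corrupted with point substitutions; single-substitution corruption is
the mechanism that makes the inexact-vs-exact comparison meaningful
synthetically, because exact 6-mer counts spread over the 18 corrupted
variants while a (6, k ≥ 1) profile re-concentrates them on the
canonical motif.

The annotation generator emits a matching CN-RCI long table over six
synthetic cell lines: each gene's class sets the sign of a ±2 log2-unit
base effect, to which per-cell-line Gaussian noise (sd 0.5) is added. A
configurable fraction of genes are planted as switching genes whose
effect sign alternates across cell lines, so their C/N counts differ by
at most one; configurable missingness drops entries without ever
orphaning a gene. Class and switching assignments are deterministic in
the gene index (class = index mod 2; the last fraction of indices
switch), so the two generators agree without shared random state.

What the fixtures do *not* emulate: real lncRNA base composition and
repeat structure, transcript-length and class-imbalance distributions
of real cell lines, correlated noise between cell lines, and biological
motif grammar. Passing the recovery tests therefore demonstrates that
the pipeline is correct and sensitive to planted sequence signal, not
that real-data accuracies are reproduced; published real-data
performance requires the external sequence and annotation downloads,
which are out of scope here.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 400 genes for the recovery and
direction checks (300 genes, single canonical motif, 3 corrupted copies
for the inexact-vs-exact harness, majority over 5 seeds) and 120–300
genes elsewhere; these sizes give stable results in minutes on one CPU
and are the package's chosen fixture conditions. Oracle sweeps use
q ≤ 4 where the naive reference is cheap. Degenerate inputs: sequences
shorter than q yield a flagged all-zero profile rather than an error;
normalizing such a profile raises with the offending transcript named.
Gradient correctness of the numpy layers is checked against central
differences.

## Known limitations

* No GPU path and no minibatch parallelism; the numpy backend is meant
  for the modest matrix sizes of this problem (≤ a few thousand rows,
  ≤ 4096 features), not large-scale training.
* The CNN on raw 4096-dim profiles is expensive on one CPU; the
  intended uses are latent (512-dim) inputs or the RF on raw profiles.
* Suffix-tree/suffix-array profile computation, gapped q-mers and
  reverse-complement canonicalization are out of scope (transcripts are
  stranded).
* `hamming_ball` memoization is per (q-mer, q, k) and unbounded growth
  is capped by the 4^q universe; for q beyond ~8 the dense profile
  representation itself becomes the limiting factor.
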