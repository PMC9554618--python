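# Methods

## Problem and model

A candidate SNV at extra-low depth is a single mismatch on a single aligned
read. The classifier decides whether that mismatch is a genuine variant or a
sequencing artifact using only (a) the read's base-level disagreement pattern
with the reference and (b) population-scale knowledge of which substitution
classes mutational processes actually produce.

**Difference encoding.** Bases map to codes A=1, T=2, C=4, G=8 (powers of
two, so every ordered pair of distinct bases yields a distinct difference).
Matched positions carry the read base's own code; mismatched positions carry
`code(ref) − code(read)`, one of {±1, ±2, ±3, ±4, ±6, ±7}. The raw values
+1, +2, +4 occur both as match codes and as differences, so each position
also records a mismatch flag and tokenization keys on the pair
(is-mismatch, value): the printed arithmetic is preserved while the token
space stays injective. The vocabulary is pad + unknown + 4 match codes + 12
differences = 18 used slots in a 20-slot embedding of dimension 5. Non-ACGT
bases map to the unknown token rather than receiving a fifth code. Reads
shorter than the configured length (default 100) are right-padded with a
dedicated pad code whose embedding is pinned at zero; longer reads are
center-cropped around the candidate position.

**Network.** The embedded read is **A** ∈ ℝ<sup>5×100</sup> with positions
as columns. A filter of region size h spans the full 100-column width and
slides along the five embedding rows, giving outputs of length 5 − h + 1 —
deliberately the transpose of the conventional text-CNN orientation, kept
because it is the declared design. Region sizes are (2, 3, 4) with 100
feature maps each; ReLU, then 1-max pooling reduces each feature map to one
scalar. The 300 pooled features plus one prior feature form the penultimate
layer feeding a 2-way softmax. Reading the architecture as one pooled
feature per region size (3 + 1 inputs) is arithmetically possible but
could not support the intended capacity; the 100-feature-maps reading is
used.

**Prior feature.** The candidate's substitution, with its reference flanks,
is canonicalized to one of the 96 pyrimidine-referenced trinucleotide
classes (purine-reference contexts are reverse-complemented). The prior is
the maximum of that class's probability across the signature-table columns,
optionally restricted to a subset of signatures (e.g. the processes active
in one cancer type), multiplied by a coefficient. The coefficient (default
7) bridges the scale gap between probabilities (~0.005–0.42) and pooled
activations; 0 disables the prior and gives the ablation model. Datasets
store the raw probability and the model applies the coefficient at forward
time, so coefficient sweeps reuse one dataset. Whether the maximum should
be taken before or after cancer-type weighting is an open modeling choice;
the unweighted maximum with an optional subset is implemented.

**Regularization and training.** Dropout applies a Bernoulli mask to the
penultimate layer during training; at inference the learned softmax weights
are scaled by the retain probability instead (classic weight scaling, not
inverted dropout). `dropout_rate` is the fraction dropped — retain
q = 1 − rate, inference scale q — so rate 0 means no dropout and the
default 0.5 coincides exactly with the mask-probability-0.5 /
scale-by-0.5 formulation. After every optimizer step each softmax weight
row with l2 norm above s (default 3) is rescaled to norm exactly s.
Training is mini-batch Adam (lr 1e-3, batch 64 — unstated upstream, chosen
as the field's defaults and configurable) under cross-entropy, with a
stratified 10% holdout driving early stopping (patience 50 iterations,
`patience=0` disables) up to `max_iters` (default 2500); the best-holdout
parameters are returned. The whole model is ~65k parameters, implemented
in numpy with hand-derived gradients; a single training run of a few
hundred iterations takes seconds on one CPU core.

## Pipeline

Candidates are extracted by walking each record's aligned (CIGAR M)
columns; insertions, deletions and clips contribute nothing and are removed
from the aligned window, which keeps the read/reference pair position-
aligned for the encoder. Coordinates are 0-based half-open internally,
1-based in SAM/VCF. Reverse-strand reads are already reference-oriented in
SAM, so no extra reverse-complementing happens at extraction; strand
symmetry is handled entirely by class canonicalization. Base/mapping
quality prefilters exist but default to off — the classifier is the filter.
Multiple reads supporting the same (chrom, pos, ref, alt) collapse into one
VCF record taking the maximum per-read probability (QUAL is its phred
transform) and recording the supporting-read count; single-read support is
sufficient by design. Site aggregation across reads is this package's
choice — the target regime has ~1 read per site, so the rule is rarely
exercised.

## Synthetic data

The generator emulates the evaluation conditions: paired-end 100 bp reads,
per-base substitution error probability 0.001 (uniform alternative base),
base qualities uniform on the inclusive ranges (33, 36) for correct bases
and (7, 19) for errors, insert sizes uniform on (0, 600) clipped up to the
read length, fragments placed uniformly, reads emitted pre-aligned with
all-match CIGARs into a coordinate-sorted SAM. Exact n× depth is built by
keeping at most n read pairs per distinct fragment start position (seeded
random choice, mates kept together). Seeded SNVs can draw their SBS96 class
proportionally to a signature table's per-class maximum, producing the
skewed spectrum of real somatic catalogs while sequencing errors stay
uniform over classes — the statistical asymmetry the prior feature exploits.
Labeling uses exact (chrom, pos, ref, alt) matching; position-only matching
would mislabel errors that land on a variant site with the wrong allele.
Class balancing is plain seeded under-/over-sampling.

Not modeled: amplification bias and its error rate (upstream parameter of
unclear units), UMIs, adapter artifacts, GC bias, indels, alignment
ambiguity, tumor purity and subclonality. Consequently, passing tests show
the method's behavior under idealized substitution-only noise with known
alignment; they say nothing about indel artifacts, mapping errors or
PCR-correlated errors in real libraries.

## Study harness and problem sizes

`detext.experiments` fixes the desk-scale study conditions: a 50 kb random
reference, 2,500 signature-skewed SNVs at VAF 1.0, ×8 raw simulated depth
extracted to ×1, all candidates labeled and balanced to 2,000 per class
(errors, the minority at this scale, are over-sampled), models trained for
250 iterations on 70/30 stratified splits. The ablation compares mean test
accuracy over five training seeds at prior coefficients 7 vs 0; the trend
study compares mean AUC over three seeds at train fractions 0.1 vs 0.7.
These sizes were chosen once as the package's single-core defaults.

Because the token sequence already determines the trinucleotide class, the
prior carries no information a perfectly trained network could not extract;
its benefit is sample- and step-efficiency, so the ablation gap is a few
accuracy points at these sizes, not the large gaps attainable with bigger
cohorts and longer training.

## Numerical choices and degenerate inputs

Convolution is validated against a double-loop oracle to 1e-9. Softmax is
computed with max subtraction; cross-entropy clips probabilities at 1e-12.
The norm constraint guards against division by zero with a 1e-12 floor and
is idempotent. Equal-base "differences" are rejected rather than coded 0;
empty reads, misaligned windows, single-class training sets, empty signature
subsets, unsorted SAM/VCF inputs and non-normalized signature columns
(tolerance 1e-6) raise descriptive errors. Undefined evaluation ratios
(e.g. precision with no positive predictions) are reported as absent, never
as 0. Stratified splits are independent seeded draws per fraction, not
rotated folds. The averaged ROC uses vertical averaging on a 101-point FPR
grid.

## Packaged signature tables

Real COSMIC tables are not bundled. Two synthetic TSVs ship instead:
`signatures_synthetic.tsv`, a two-signature table with mass concentrated on
C>T and T>G classes, and `cosmic_max_synthetic.tsv`, a single-column table
embedding the two published extreme per-class maxima (A[C>G]G at 0.005275,
T[C>T]A at 0.41994, a 79.6-fold spread) in an otherwise uniform normalized
column. Both are synthetic stand-ins for lookup-path tests and simulations;
any real SBS table in the documented TSV dialect drops in.
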