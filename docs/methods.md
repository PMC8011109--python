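# Methods

## The model

`tsplice` models tissue-specific alternative splicing of cassette exons. For
exon *e* and tissue *t*, let Ψ_e,t ∈ [0,1] be the percent spliced-in and
Ψ̄_e the arithmetic mean of Ψ over observed tissues, taken on the natural
scale (averaging before the logit transform is more robust when Ψ is near
the boundaries). The quantity the network predicts is the tissue-associated
differential splicing

    Δ_tissue logit(Ψ_e,t) = logit(Ψ_e,t) − logit(Ψ̄_e),

one value per tissue, from sequence alone. Tissue-level Ψ is reconstructed
as Ψ̂_e,t = σ(Δ̂_e,t + logit(Ψ̄_e)). All logits clip their argument into
[10⁻⁵, 1−10⁻⁵]; the clipping constant is applied identically everywhere
(targets, offsets, predictions), so round-trips are exact away from the
boundary.

### Inputs

Four windows around the exon, always in transcript orientation: 300 nt of
upstream intron ending at the acceptor, the first 100 nt of the exon, the
last 100 nt of the exon, and 300 nt of downstream intron starting at the
donor. Exons shorter than 200 nt contribute overlapping exon windows; exons
shorter than 100 nt are zero-padded on the exon-interior side — this keeps
both splice-site contexts intact, which is where the positional signal
concentrates. Sequences are one-hot encoded (columns A, C, G, T); N bases
and pad positions are all-zero rows and therefore contribute nothing to the
convolution. Minus-strand exons are reverse-complemented during extraction,
so the model never sees strand.

### Architecture

Two 400×4 branches (acceptor-side: upstream intron + exon start; donor-side:
exon end + downstream intron) pass through:

1. a shared 1D convolution, 64 filters of length 9, same padding, bias,
   ReLU — shared because many splicing motifs act on both sides of an exon;
2. batch normalization (shared scale/shift, since the convolution is shared);
3. per-branch positional weighting: the activation of filter *f* at position
   *p* is multiplied by w_f(p) = Σ_b θ_{f,b}·B_b(p), where B is a clamped
   uniform cubic B-spline basis with 10 functions over the 400 positions.
   The basis rows form a partition of unity, so initializing θ ≡ 1 makes the
   weighting an exact identity at the start of training. Weighting is
   multiplicative per filter with no positional bias term; the two branches
   have independent θ because upstream and downstream positional effects
   differ;
4. per-branch batch normalization;
5. concatenation along the position axis (800×64) and global average pooling
   over positions (→64);
6. a dense layer of 32 units with ReLU and batch normalization;
7. a linear output layer with one unit per tissue (default 56).

Batch-normalization scale and shift count as trainable parameters; running
statistics do not. The default configuration totals exactly 8024 trainable
parameters: 64·37 (conv) + 128 (BN) + 2·640 (splines) + 256 (branch BNs)
+ 2080 + 64 (hidden) + 1848 (head). Hidden width (32), spline basis count
(10), the ReLU choices and the batch-normalization placement are not
independently identifiable from the architecture sketch alone; the
configuration used here is the small one consistent with that printed total,
and it is fixed as the package default.

The network is implemented directly in numpy with explicit forward and
backward passes (verified against central finite differences to ~1e-8 in
float64). At 8024 parameters this trains comfortably on one CPU; there is no
GPU path.

### Training

The loss is the masked Kullback–Leibler divergence between measured and
predicted inclusion, treating Ψ as the probability that a transcript
includes the exon:

    Loss = 1/(T·E) Σ_{t,e} γ_e,t [ Ψ log(Ψ/Ψ̂) + (1−Ψ) log((1−Ψ)/(1−Ψ̂)) ],

with γ_e,t = 1 where Ψ is observed. Missing entries (typically tissues where
the gene is not expressed) contribute zero to the numerator; the denominator
is deliberately the full T·E — an observed-count denominator would only
rescale the gradient. The loss is bitwise invariant to values stored at
masked entries.

Optimization: Adam with default hyperparameters (lr 10⁻³, β₁ 0.9, β₂ 0.999),
minibatches of 64, He-normal weight initialization, early stopping on
validation loss with patience 10, best-validation parameters restored. Data
splits by chromosome: validation {1, 7, 9}, test {2, 3, 5}, everything else
(including the sex chromosomes) trains; unrecognized contigs go to the
training set with a warning.

Ensembling: several networks are trained from independent initializations
(default 20; tests use fewer), sorted by validation loss, and greedily added
to a running average on the Δ_tissue logit scale while the ensemble's
validation loss strictly improves. The ensemble's validation loss can
therefore never exceed the best single model's.

## Variant effects

A tissue-agnostic scorer supplies one Δlogit(Ψ) per allele change (the
package bundles a zero scorer and a file-backed scorer keyed by variant id;
any model satisfying score(S,S)=0 plugs in). The combined tissue-specific
prediction is additive on the logit scale:

    ΔΨ_e,t = σ( logit(Ψ̄_e^ref) + score(S_ref, S_alt) + TSplice(S_alt)_t ) − Ψ_e,t^ref,

and the tissue-agnostic prediction omits the network term. When the measured
per-tissue reference Ψ is unavailable, the model's own mode-consistent
reference prediction substitutes (σ of the same logit expression evaluated
on the reference allele), and the per-tissue source is recorded in the
output. Only SNVs are handled; variants in the deep exon interior (beyond
the first/last 100 nt of exons longer than 200 nt) are outside every input
window and are returned unchanged with an `unmodeled` flag.

Cohort ΔΨ for one exon×tissue cell is the mean Ψ of samples homozygous for
the alternative allele minus the mean Ψ of samples homozygous for the
reference allele, requiring at least 2 samples per group. Heterozygotes are
excluded because their Ψ is confounded by allele-specific expression.

Benchmark filtering of a variant × tissue ΔΨ table supports two modes:
per-variant (keep variants with |ΔΨ_t − mean_t ΔΨ| > 0.2 in ≥1 tissue and ≥3
defined tissues, then tissues with strictly more than 10 surviving variants)
and per-cell (keep only cells exceeding the deviation threshold, tissues
with ≥10 such cells). Thresholds use strict inequality. Variant→exon
mapping uses the exon body ±300 nt window; a variant mapping to several
exons reports the largest-magnitude score with its sign; an optional
|Δlogit(Ψ)| > 0.05 retention filter and a LOEUF < 0.35 intolerance grouping
support burden-style downstream analyses.

## Motif insertion maps and attributions

In-silico mutagenesis substitutes a splicing-factor consensus (defaults:
TCAT for NOVA1/2, TGCATG for RBFOX1, GCTTGC for MBNL1) at every position of
one input region across a seeded sample of exons, and reports the per-tissue
mean difference between mutated and native predictions. "Insertion" is
length-preserving substitution — the inputs have fixed geometry, so true
insertion would shift every downstream position. Windows that already read
the consensus score exactly zero by construction (the substitution is the
identity there), short-circuiting the forward pass. Gradient×input
attributions multiply the inference-mode input gradient (a chosen tissue or
the tissue mean) by the one-hot input; pad and N rows get zero attribution.
Gradient×input is not a complete attribution method; only its zero-input and
local-linearity properties are relied on.

## Ridge baseline

Per tissue, an L2-regularized linear model on shared sequence features
predicts the same logit deviation with the logit tissue-average as a fixed
offset. Features: counts of overlapping motif occurrences (step-1 sliding
window) of the three consensus motifs plus all 64 {A,T} hexamers
(PTBP-class) in each intron, the consensus motifs plus an optional
user-supplied exonic-regulator hexamer list in the exon body (the full body,
not just the network's 100-nt windows — these features are not tied to the
network's input geometry), and one-hot splice-site contexts (acceptor: 20
intronic + 3 exonic nt; donor: 3 exonic + 6 intronic nt). The "{A,T}
hexamer" reading of the PTBP-class family is ambiguous in the literature
(pyrimidine C/T words would also be defensible); the alphabet is
configurable and {A,T} is the default. The intercept and the offset are
unpenalized; features are raw counts (not standardized) by default. λ is
chosen per tissue by 5-fold seeded cross-validation over a 10⁻³…10³ grid.
Tissues with fewer than two observed exons are skipped with a warning.

## Synthetic data

The generator emulates the structure such models are trained on without any
download: i.i.d. uniform background sequence, exon bodies 120–280 nt with
300-nt intron flanks, both strands, exons laid out across 23 named
chromosomes so the chromosome split applies; per-exon base Ψ drawn
logit-normally (mean 0, sd 1); a planted consensus motif (default: TCAT in
the upstream intron, carried by half the exons) shifting a tissue block
(default tissues 0–2 of 8, "brain-like") by a fixed logit effect (default
−1); logit-normal measurement noise (sd 0.3); 10% missingness with at least
one observed tissue per exon. Chance occurrences of every configured
consensus are scrubbed from the background before planting, so the recorded
truth is consistent with the emitted sequences — with a 4-mer, about 1.2
chance hits would otherwise occur per 300-nt intron. The recorded truth
(carrier status, motif positions, noiseless Ψ, true Δ_tissue logit) satisfies
the mean-deviation identity exactly at zero noise.

What the generator does not emulate: dinucleotide composition, real
splice-site strength, correlated noise across tissues, population LD in
cohorts. Passing recovery tests therefore demonstrates that the estimation
machinery works under the stated generative model, not that the defaults
reach any particular accuracy on real catalogs.

The cohort generator assigns homozygous-reference / heterozygous /
homozygous-alternative groups by rounded frequencies (default 0.25/0.5/0.25
over 40 samples), shifts homozygous-alternative Ψ by the variant's logit
effect, and errors out if either homozygous group would have fewer than two
samples. At zero noise the cohort estimator recovers
σ(logit(p)+effect) − p exactly.

## Problem sizes used in the test suite

The recovery experiment trains the default 8-tissue network on 1400 of 2000
synthetic exons (200 validation, 400 held out) for at most 50 epochs — a
few minutes on one CPU — and evaluates (i) validation loss against the
zero-output baseline, (ii) Spearman correlation between predicted and true
Δ_tissue logit on the held-out exons, and (iii) the insertion score map of
the planted motif (150 sampled held-out exons). A known property of the
block design: with 3 of 8 tissues affected, the mean-deviation definition
forces the non-affected tissues to respond with ≈ 3/5 of the affected-tissue
magnitude and opposite sign — measured on the generated data the ratio is
0.557 — so the motif's effect can be localized in sign but the non-affected
response is not small relative to the affected one at this block fraction
(it shrinks as b/T does; at a 5-of-56 block it would be ≈ 0.1).

## Numerical choices

- float32 parameters and activations; Adam moments in float64.
- Batch-norm ε 10⁻³, running-statistic momentum 0.1.
- Partition-of-unity spline rows exact to 10⁻¹⁰; θ ≡ 1 at init so positional
  weighting starts as the identity.
- Ties in ensemble selection broken by stable sort order (training order).
- Degenerate inputs: all-missing Ψ rows are rejected; exons with no observed
  tissue cannot define Ψ̄.
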