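# Methods

## Model

`g4vivo` treats in vivo G4 formation as supervised binary classification
over in vitro candidate sites. For candidate i with feature vector
xᵢ = (aᵢ, sᵢ) — accessibility bins aᵢ ∈ ℝ²⁰⁰ and ordinal base codes
sᵢ ∈ {0..4}²⁰⁰⁰ — a gradient-boosted tree ensemble F(x) = Σₘ fₘ(x) is fit by
LightGBM to the binary log-loss, and P(active|x) = σ(F(x)). Sequence columns
are declared categorical: at each split the learner orders the observed base
categories by objective statistics and finds the best binary partition, so
no ordering of {A,T,C,G} is imposed and no one-hot expansion (which grows
trees poorly) is needed.

The core assumptions, in decreasing order of importance:

* local chromatin accessibility is the dominant determinant of whether a
  sequence-competent G4 folds in vivo;
* that relationship is shared across cell types, so a model trained on one
  cell line transfers to another given that cell line's ATAC track;
* a 2 kb window centered on the candidate captures the relevant context.

## Coordinates and I/O

Everything is BED-native 0-based half-open. Candidate windows are anchored
at the floor midpoint `start + len//2` (the convention for odd lengths is a
package choice; nothing downstream is sensitive to the 1 bp ambiguity).
Windows that run off a chromosome end are padded — `N` for sequence (encoded
as the unknown category 4), `0.0` for signal — rather than rejected, so
candidates near contig edges keep the fixed 200 + 2000 feature width; a
warning is logged per padded fetch. Soft-masked lowercase bases are
uppercased; masking state is discarded. Signal tracks may be bigWig or
bedGraph (sniffed by extension, overridable); bedGraph carries no sizes
header, so sizes default to the last covered position unless supplied.

## Labeling

A candidate is active iff some in vivo peak overlaps it by at least
`overlap_fraction` (default 0.10) of the reference length. The reference is
the *peak* by default, with the *candidate* available via configuration —
the two readings circulate in the field's descriptions of this rule and
differ for long peaks over short candidates, so both are first-class.
Comparison is inclusive (≥); ties at the threshold count as overlap. A
`summed` aggregation mode compares total overlap across peaks against the
candidate-relative threshold (a peak-relative summed threshold is
ill-defined and rejected). Strand is ignored, matching standard unstranded
peak intersection.

## Strand orientation

Whether features should be read 5'→3' on the candidate strand is genuinely
open; `strand_orient=True` is the default (minus-strand sequence
reverse-complemented, accessibility vector reversed) so G-tract patterns are
strand-consistent, and the flag is recorded in the model's feature schema so
a model trained one way refuses features built the other way.

## Balancing protocol

`stratified_half_split` draws, per class, `floor(train_fraction · n_class)`
members uniformly without replacement into the training half; the remainder
(the extra member of an odd class) goes to the test half. This floor/ceil
convention is what makes an odd class count produce the characteristic
train/test asymmetry (e.g. 2491 positives → 1245 train / 1246 test).
`oversample_positives` duplicates uniformly drawn positive rows (with
replacement) until the classes are equal — duplication only, never synthetic
interpolation, so every training feature vector is a real observation. The
test half is never balanced. All randomness flows through explicitly seeded
NumPy generators; repeated evaluation uses seeds `base .. base+k−1` (k = 5
by default) and reports mean ± SE with SE = sd(ddof=1)/√k, reseeding both
the split and the training.

## Hyperparameters

The defaults are `n_estimators=500`, `learning_rate=0.1`, `num_leaves=31`,
`min_child_samples=20`, `feature_fraction=0.5`, single-threaded and
deterministic. The column-subsampling default deserves explanation: after
oversampling, a small study can contain few *distinct* positive rows, and
then many individual accessibility bins separate the training classes
perfectly. Greedy tree induction is free to choose any of them, including
bins where the class gap is a razor-thin margin over noise, and a
deterministic ensemble built on full columns can stack hundreds of trees on
the same fragile threshold. Giving each tree a random half of the columns
forces the ensemble to average over many bins, which restores the
large-margin behaviour one expects from the planted signal. All parameters
are overridable via the flat config file, and the full effective set is
logged into the model's provenance. Training with `n_jobs>1` is allowed but
logs a warning that bit-reproducibility is relinquished.

## Metrics

Accuracy, precision, recall and F1 come from the confusion matrix at a
score threshold with the ties-to-positive rule (call = 1 iff score ≥ t).
Precision, recall and F1 with a zero denominator are reported as NaN —
an all-negative predictor has undefined precision, and hiding that as 0
would silently deflate averages. AUROC is the trapezoidal area under the
tie-grouped ROC sweep (identical to the rank statistic with ties counted
half). AP is the step sum Σ(Rₙ−Rₙ₋₁)Pₙ over the same sweep anchored at
recall 0 — deliberately not the PR trapezoid, which is a different (and
optimistically biased) quantity. Both implementations are cross-checked in
the test suite against exhaustive pair-counting/threshold-sweep oracles and
against scikit-learn.

## Synthetic studies

The generator emulates the *shape* of a real cell-line study: an i.i.d.
uniform-ACGT genome (4 × 2 Mb by default); 2000 planted candidates, each a
G4-like motif (four G₃ tracts, random 2–7 nt loops) written onto a random
strand at centers ≥ 2 kb apart and ≥ 1.1 kb from chromosome ends; a
Bernoulli(0.01) active subset (the ~1% skew of real candidate pools); an
accessibility track of blocky half-normal noise (sd 0.25 per 20 bp block)
plus a Gaussian bump (height 4, sd 150 bp) on each active center; and one
150 bp in vivo peak centered on each active candidate. The peak half-width
(75 bp) is deliberately paired with the motif geometry: the 10% peak-length
threshold is 15 bp, below the shortest plantable motif (18 bp), so default
labeling recovers the planted truth exactly — a construction guarantee, not
an empirical accident. Ground truth lives in a separate `truth.tsv` that no
pipeline command reads, so leakage is structurally impossible.

What the generator does *not* emulate: fragment-level ATAC read sampling,
nucleosome structure, GC/mappability bias, overlapping or nested candidate
entries, and any sequence difference between active and inactive candidates
(by default both carry the same motif family, so sequence-only models have
nothing to learn — mirroring the empirical weakness of sequence-only
prediction — and the ablation tests have a known answer). An optional
`seq_bias` mode plants a discriminative base at a fixed motif offset when a
non-trivial sequence-only signal is wanted. Passing tests on synthetic data
therefore demonstrate the pipeline's correctness and its ability to recover
a planted accessibility effect at realistic skew — not performance on real
chromatin.

Problem sizes in the test suite and acceptance script are the generator
defaults above (2000 candidates over 8 Mb) for the headline recovery runs,
and a 150-candidate single-chromosome variant with softened skew (15%
active) for unit-level fixtures, which keeps both classes populated at
small n.

## Degenerate inputs and numerical notes

Empty feature matrices predict an empty score vector; single-class training
data, empty site sets for profiling, a zero-length BED interval, and a
summed+peak labeling configuration are errors. Window means use exact
per-base expansion with zero fill. Model persistence is a single JSON file
(LightGBM model string + feature schema + provenance); a reloaded model
reproduces scores bitwise. Feature-schema digests (column count, categorical
mask, mode, geometry, orientation) guard every prediction path.

## Known limitations

* Desk-scale positive counts (tens) are far below the thousands in real
  cell lines; metrics at the default synthetic scale have wide sampling
  variability, which is why the zero-effect control uses a denser active
  fraction (5%) for a usable chance-level estimate.
* The bedGraph reader materializes dense per-chromosome arrays; it is meant
  for desk-scale tracks, with bigWig as the random-access backend for
  genome-scale data.
* Labeling is resolution-limited by the in vivo peaks themselves; the model
  predicts peak-supported activity, not G4 folding thermodynamics.
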