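# g4vivo

Cell-type-specific prediction of in vivo G-quadruplex (G4) formation from
chromatin accessibility and sequence.

## The problem

G4-seq detects hundreds of thousands of DNA sequences that can fold into
G-quadruplexes in vitro, but antibody-based in vivo assays (G4 ChIP-seq, G4
CUT&Tag) find only ~10⁴ of them actually folded in any given cell line. Which
in vitro candidates are *active* in a particular cell type is therefore a
heavily imbalanced binary classification problem (~1% positives), and the
deciding factor is largely the local chromatin environment rather than the
sequence itself.

`g4vivo` is for genomics researchers who have a candidate G4 set (BED), an
ATAC-seq signal track (bigWig/bedGraph), and — for training — an in vivo G4
peak set for at least one cell line, and who want to map the in vivo G4
landscape of cell lines that lack in vivo G4 data.

## Method

1. **Labeling.** A candidate interval is labeled active when it overlaps an
   in vivo peak by ≥ 10% of the peak's length (the reference length and the
   aggregation rule are configurable).
2. **Features.** Each candidate is extended to a 2 kb window about its
   center. The window yields x = (a, s): a ∈ ℝ²⁰⁰, the mean ATAC signal in
   200 non-overlapping 10 bp bins, and s ∈ {0,…,4}²⁰⁰⁰, the per-base ordinal
   codes A→0, T→1, C→2, G→3 (other→4). Minus-strand candidates are
   reverse-complemented and their signal vector reversed.
3. **Classifier.** A gradient-boosted decision-tree ensemble (LightGBM) with
   the 2000 sequence columns declared *categorical*, so each split orders
   the base categories by training objective instead of the arbitrary
   numeric order. P(active | x) is the ensemble's logistic output.
4. **Protocol.** Class-stratified 50/50 split; positives in the training
   half are oversampled by duplication to match the negatives; the test half
   is never balanced. Metrics: accuracy, precision, recall, F1 at a score
   threshold (0.5 by default), AUROC, and step-sum average precision
   AP = Σₙ (Rₙ − Rₙ₋₁) Pₙ, reported as mean ± SE over repeated seeds.
   One-cell-line (train/test same cell line) and cross-cell-line (train on
   one, test on another) experiment drivers are built in.

A synthetic-study generator produces a miniature genome, planted G4-motif
candidates, an accessibility track with Gaussian bumps on the active subset,
and centered in vivo peaks, so the whole pipeline is testable end to end
without any downloads.

## Worked example

```python
from g4vivo import (SyntheticConfig, generate_synthetic_study, label_entries,
                    build_feature_matrix, LabeledDataset, G4ActivityModel,
                    stratified_half_split, oversample_positives, SplitSpec)

cfg = SyntheticConfig(n_chroms=1, chrom_length=400_000,
                      n_candidates=150, active_fraction=0.15)
study = generate_synthetic_study(cfg, seed=7)

labeled = label_entries(study.candidates, study.invivo)
fm = build_feature_matrix(labeled, study.track, study.genome)
ds = LabeledDataset.from_labeled_candidates(labeled, fm)

train, test = stratified_half_split(ds, SplitSpec(seed=0))
balanced = oversample_positives(train, seed=0)
results = G4ActivityModel(balanced).fit(seed=0)
print(results.summary())
print(results.evaluate(test, threshold=0.5).summary())
```

prints

```
G4 activity model (gradient-boosted trees)
  features: both (2200 columns, 2000 categorical)
  flank=1000 window=10 strand_orient=True
  trained on 120 rows (60 positive), seed 0
  hyperparameters: n_estimators=500, learning_rate=0.1, num_leaves=31, min_child_samples=20, feature_fraction=0.5, n_jobs=1
  top features by gain: atac_70 (465), atac_73 (221), atac_71 (79), atac_74 (55), atac_72 (52)
evaluation at threshold 0.5 (n=76, positives=15)
  TP=15 FP=1 TN=60 FN=0
  accuracy  0.9868
  precision 0.9375
  recall    1.0000
  f1        0.9677
  auroc     1.0000
  ap        1.0000
```

The model's most informative features are accessibility bins near the window
center (`atac_70`–`atac_74`), exactly where the generator planted its
accessibility bumps; on the held-out half it recovers every active candidate
(recall 1.0) with one false positive.

The same pipeline is available from the shell:

```sh
g4vivo simulate --out study --seed 7
g4vivo label --candidates study/candidates.bed --invivo study/invivo_peaks.bed -o labeled.bed
g4vivo extract-features --bed labeled.bed --atac study/atac.bedgraph \
    --genome study/genome.fa -o features.tsv
g4vivo experiment --design one-cell --features features.tsv --repeats 5 -o report.json
```

## Real data

The method was developed against public human data: G4-seq candidates
(GEO GSE110582, K⁺ condition), G4 ChIP-seq peaks for K562/HepG2
(GSE107690, GSE145090), G4 CUT&Tag peaks for MCF7 (GSE181373), and ENCODE
ATAC-seq tracks (ENCFF357GNC, ENCFF262URW, ENCFF976UNK), on hg19. Those
accessions are *not* bundled or downloaded here; any BED + FASTA + signal
track triple with consistent chromosome names works. `g4vivo profile`
aggregates any signal (e.g. histone-modification tracks) around predicted G4
sites for downstream chromatin-state analysis.

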