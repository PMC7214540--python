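# thermoraac

Sequence-based recognition of thermophilic proteins from mixed descriptors
over a reduced amino acid alphabet.

Thermostable enzymes are a central target of protein engineering, and the
amino acid composition of proteins from thermophilic organisms differs
systematically from that of mesophilic ones (enrichment of charged residues
such as Arg, Lys and Glu; depletion of thermolabile residues such as Gln and
Met). `thermoraac` turns this signal into a classification pipeline for
researchers who have labeled protein sequences (thermophilic vs
non-thermophilic, in FASTA form) and want a reproducible, inspectable
predictor together with a report of which sequence features carry the
signal.

## Method

For each validated protein sequence `s` of length `L` over the 20 standard
amino acids, three descriptor families are extracted and concatenated:

1. **188D physicochemical descriptor** — 20 amino acid frequencies; then,
   for each of 8 physicochemical properties with a conventional three-group
   split of the alphabet: 3 group compositions, 15 distribution values (the
   normalized positions of the 1st/25%/50%/75%/100% occurrences of each
   group), and 3 cross-group transition rates (counts / (L − 1)). Total
   20 + 24 + 120 + 24 = 188.
2. **Gapped reduced dipeptides** — the sequence is recoded onto a 19-symbol
   alphabet (Ile and Val merged, represented by V), and λ-gap dipeptide
   frequencies are computed for λ ∈ {0, 1, 2}:
   `f_λ(j) = y_λ(j) / Σ_j y_λ(j)`, where `y_λ(j)` counts ordered symbol
   pairs separated by λ positions. 19² = 361 slots per gap, 1083 in total.
3. **Auto-cross covariance (ACC)** — for standardized numeric property
   traces `S_i` along the sequence,
   `AC(i, g) = 1/(L − g) · Σ_j (S_{i,j} − S̄_i)(S_{i,j+g} − S̄_i)` and the
   analogous two-property `CC(i1, i2, g)`, for lags g ∈ {1, 2} over 3
   scales: 18 features.

The 1289-column matrix is then reduced in three stages:

1. **Correlation pruning** — columns are min-max normalized to [0, 1]; every
   pair with |Pearson ρ| > T (default 0.85) feeds a removed set D and a
   reserved set R through a fixed, order-deterministic rule table, and the
   columns in D are dropped.
2. **MRMD selection** — features are ranked by MR + MD (relevance: |Pearson
   correlation with the class vector|; distance: mean Euclidean distance to
   the other columns), and the ranking is truncated at the smallest top-k
   subset maximizing cross-validated accuracy.
3. **PCA** — the retained columns are projected onto the smallest number of
   principal components whose cumulative eigenvalue contribution reaches T′
   (default 0.95).

The component matrix is evaluated under stratified 10-fold cross-validation
with an RBF-kernel SVM (and optionally random forest, decision tree, naive
Bayes), reporting sensitivity `Sn = TP/(TP+FN)`, specificity
`Sp = TN/(TN+FP)`, accuracy `ACC = (TP+TN)/total` (as percentages, pooled
over folds) and the ROC curve from held-out scores.

A bundled synthetic-sequence generator produces labeled datasets with a
tunable composition separation δ (positives tilted +δ on K/R/E and −δ on
Q/M, negatives oppositely), so the whole pipeline is testable and
calibratable without any external download.

## Worked example

```
python examples/03_full_pipeline.py
```

generates a balanced synthetic dataset (100 + 100 sequences, δ = 0.06),
runs the full pipeline, and prints:

```
stage dimensions: {'extract': 1289, 'normalize': 1289, 'prune': 1224, 'mrmd': 36, 'pca': 23}
svm: 10-fold CV — Sn 100.00%  Sp 100.00%  ACC 100.00% (fold mean 100.00 ± 0.00)  AUC 1.0000
naive_bayes: 10-fold CV — Sn 96.00%  Sp 98.00%  ACC 97.00% (fold mean 97.00 ± 4.83)  AUC 0.9864
Top retained features (by MRMD total):
    1  CTDD|charge|G2|p100            MR=0.3477 MD=11.3036
    ...
Removed dipeptide pairs collapsed over gaps (multiplicity >= 2):
  MM: 3
  MQ: 3
  QQ: 2
```

Reading the output: the mixed matrix starts at 1289 columns; pruning removes
65 redundant ones, MRMD keeps the 36 best-ranked features, and PCA
compresses them to 23 components. On this well-separated synthetic data the
SVM recovers the classes perfectly; the removed-feature report shows the
collapsed dipeptide pairs (here MM, MQ, QQ — pairs of the depleted residues,
whose near-constant columns carry little usable signal) dropped by the
correlation stage. `examples/01`, `02` and `04` walk the individual stages:
feature extraction for a single sequence, the reduction stages with their
intermediate dimensions, and the calibration of δ against the analytic
accuracy bound of the generator.

Real data enter either as two per-class FASTA files or one FASTA plus a
two-column `id<TAB>{0,1}` TSV; `sample_balanced` draws the balanced
subsample (e.g. 500 + 500) used for training. The same pipeline is exposed
as a CLI:

```
thermoraac simulate --n-pos 100 --n-neg 100 --out-dir data/
thermoraac run --n-pos 300 --n-neg 300 --delta 0.06 --out-dir runs/demo
thermoraac report --run-dir runs/demo
```

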