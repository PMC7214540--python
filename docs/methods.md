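# Methods

This note documents the model, the tunable parameters, the synthetic data
generator, and the numerical and design choices behind `thermoraac`.

## Problem and model

The task is binary classification of protein sequences: thermophilic
(label 1, the positive class throughout) vs non-thermophilic (label 0).
The method assumes the signal is carried by sequence-intrinsic statistics —
residue composition, short-range residue pairing, and the layout of
physicochemical classes along the chain — rather than by homology or
structure. Accordingly every input is a plain amino acid sequence over the
20-letter alphabet; nonstandard residues (B, J, O, U, X, Z) are rejected by
default (`strict` policy) or dropped per record (`drop-record`), because the
descriptors below are defined only over the standard alphabet.

### Feature families

**Reduced alphabet.** The default 19-class scheme merges Ile and Val into a
single class represented by `V` and keeps every other residue as its own
class; it derives from clustering amino acids by substitution behavior. The
6-class Dayhoff grouping (`AGPST | DENQ | HKR | ILMV | FWY | C`) and the
identity map are built in; custom schemes load from a one-group-per-line
text file. Reduction is applied **only** to the dipeptide family: the 188D
blocks explicitly include original-alphabet frequencies, and the ACC traces
are property values of the original residues, so both are computed on the
unreduced sequence.

**Gapped dipeptides.** For gap λ, `y_λ(a, b)` counts positions `i` with
`s[i] = a` and `s[i+1+λ] = b`; frequencies are normalized **within each
gap** by `Σ_j y_λ(j) = max(L − 1 − λ, 0)`, so each gap block sums to 1
whenever countable. Per-gap normalization (rather than a single global
denominator) is forced by reading the normalizing sum as running over
dipeptide types at fixed gap; per-gap totals differ, so a global denominator
would break the sum-to-one property. Sequences too short for a gap get an
all-zero block flagged `uncountable` plus a logged warning, keeping feature
matrices rectangular instead of entangling extraction with dataset
filtering. Column order is bit-stable: gap ascending, then first and second
symbol in the scheme's declared group order; names are `RD|λ|a|b`.

**188D descriptor.** Blocks: (1) 20 residue frequencies in
`ACDEFGHIKLMNPQRSTVWY` order; (2–4) for each of 8 properties with a 3-group
partition: composition (group fractions), distribution, and transition.
The distribution convention is: positions are 1-based and divided by `L`;
the p% occurrence is the `ceil(p · n_g)`-th occurrence of the group
(`n_g` = occurrences of that group), with the first occurrence reported in a
separate slot and five zeros for an absent group. Transitions count
unordered adjacent cross-group pairs (G1↔G2, G1↔G3, G2↔G3) divided by
`L − 1`; a length-1 sequence yields a zero transition block with a warning.
The 8 properties (hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, surface tension, secondary-structure propensity,
solvent accessibility) and their conventional 3-group splits are shipped as
a TSV data file (`data/ctd_groups.tsv`) and are swappable without code
changes, since different published variants of this descriptor disagree on
the exact tables.

**ACC.** Three numeric scales — hydrophobicity, hydrophilicity, side-chain
mass (`data/acc_scales.tsv`) — are standardized to zero mean / unit variance
over the 20 amino acids and mapped along the sequence. For lag `g`:

    AC(i, g) = 1/(L − g) · Σ_{j=1..L−g} (S_{i,j} − S̄_i)(S_{i,j+g} − S̄_i)

with `S̄_i` the **per-sequence** mean of the trace, making AC a true
autocovariance (zero for any constant trace, invariant under sequence
reversal); CC is the same product with two different scales. The divisor is
`L − g`, matching the number of summed terms. N = 3 scales with max lag
lg = 2 give 3·2 AC + 3·2·2 CC = 18 features; the scale count and identities
are configurable, and N = 3, lg = 2 is the default because it is the small
configuration consistent with the 18-feature ACC family the pipeline is
designed around.

### Reduction stages

**Normalization** is min-max per column: `(x − x_min)/(x_max − x_min)`;
constant columns map to zeros with a warning. (A mean-centered numerator
would contradict the stated [0, 1] target range, so the min-max form is
used.)

**Correlation pruning.** Pearson correlation uses the standard sample
convention; zero-variance vectors correlate 0 by convention with a warning.
Unordered pairs are scanned in canonical order — upper triangle, row-major
— and each pair with |ρ| > T (default T = 0.85; 0.90/0.95 are sensible for
corpora with globally stronger correlation) feeds the rule table in
`correlation_prune`'s docstring. Determinism choices: the first pair's
members are assigned earlier-column → R, later-column → D (the choice is
symmetric for the pair itself, and a deterministic rule makes runs
replayable); the processing order matters because the rules are stateful,
so it is fixed to column order. Pairs whose members are both already
assigned trigger no rule in the default (literal) mode; `strict=True` adds a
pass that demotes the later member of any still-correlated retained pair,
guaranteeing no two kept columns exceed T.

**MRMD.** Relevance `MR_i = |ρ(F_i, C)|` (class vector as 0/1 reals) and
distance `MD_i` = mean Euclidean distance from column i to every other
column, both on normalized columns; ranking is by `MR + MD` descending with
ties broken by feature name. Note the scale asymmetry: MR ≤ 1 while MD
grows like √n_samples, so at realistic n the ranking is distance-dominated;
this is a documented property of the criterion as defined, not an artifact.
Subset truncation evaluates cross-validated accuracy of the pipeline's SVM
on the top-k features and returns the smallest k attaining the maximum
observed accuracy. The full sweep over every k is the literal reading and
is available (`mrmd_patience=None`); the default run mode stops after 50
consecutive non-improving k. Patience 50 was chosen because much smaller
values can quit at an early local maximum of the greedy trace and miss the
global one the full sweep finds, while 50 tracked the full-sweep result in
every condition we exercised at a fraction of the cost. The selection CV
uses a fold seed derived independently from the final evaluation's fold
seed, limiting the feedback between subset choice and reported accuracy.

**PCA** centers the (already reduced) columns and eigendecomposes via SVD;
eigenvalues are `s²/(n−1)`. k is the smallest value with cumulative
eigenvalue share ≥ T′ (default 0.95), unless `k_override` fixes it (error
beyond the data rank). Sign convention: each axis's largest-magnitude
loading is made positive, so models and projections are reproducible.

### Evaluation

Stratified k-fold cross-validation (default 10 folds), deterministic per
seed; stratification keeps per-fold class ratios within one observation of
the global ratio, stabilizing Sn/Sp at the ~1000-sample scale. Sn/Sp/ACC are
reported primarily from pooled fold confusion counts, with fold mean ± sd
secondary, since the two can differ and neither convention is universal.
Sn (or Sp) is reported as not-applicable rather than 0 when its class is
empty. ROC curves use the models' continuous scores (decision function, or
positive-class probability where no decision function exists) on held-out
observations pooled across folds; the area is the trapezoid rule. Classifier
hyperparameters are near-default on purpose — RBF SVM with C = 1 and
γ = 1/n_features, 100-tree random forest, default decision tree and Gaussian
naive Bayes — and exposed via configuration; the method's claims do not rest
on tuning.

## Synthetic data generator

The generator emulates a balanced two-class corpus of the kind used to
train this pipeline: n_pos + n_neg i.i.d.-per-position random sequences with
lengths uniform on 100–600. Class separation is a single parameter δ:
positives add +δ to the K, R, E probabilities and −δ to Q, M before
renormalization; negatives apply the opposite tilt (so the between-class
difference per biased residue is 2δ). The base composition gives each of
the five biased residues 7% — toward the top of the range abundant residues
occupy in real proteomes — and spreads the remaining 65% uniformly, so the
documented tilt range δ ∈ [0, 0.07) always yields valid probability
vectors; any δ that would drive an entry negative raises before generation.

`expected_separation` converts a spec into the balanced Bayes accuracy of
the optimal per-residue log-likelihood-ratio classifier, treating the LLR of
a mean-length sequence as normal under each class. It is an upper reference
for calibrating δ grids: the pipeline is not that classifier, so its
accuracy sits at or below the bound (markedly below at small δ, where the
distance-dominated MRMD ranking spends part of the subset budget on
uninformative columns).

What the generator does **not** emulate: real positional dependence
(secondary structure, domains), homology between sequences, realistic
global composition, or any dipeptide-order signal in the default i.i.d.
mode. An optional first-order Markov mode (`markov_coupling`) plants
class-specific self-repeat coupling so the dipeptide family carries signal
beyond composition, which lets tests attribute which family detects which
planted structure. Consequently, passing results on synthetic data
demonstrate that the pipeline recovers planted compositional separation and
stays at chance under the null — not that it attains any particular accuracy
on real thermophile corpora.

## Problem sizes and defaults

- Study-scale runs (tests and the reproduction script): 300 + 300
  sequences, lengths 100–600, δ grid {0, 0.01, 0.03, 0.06}; chosen as the
  scale at which the pipeline's behavior is stable while a full grid run
  completes in about a minute.
- `T = 0.85`, `T′ = 0.95`, `lg = 2`, `max_gap = 2`, 10 folds, SVM first:
  the pipeline's canonical operating point.
- One master seed per run is expanded via `SeedSequence.spawn` into
  independent sub-seeds for subsampling, generation, selection folds and
  evaluation folds, so stages are individually reproducible and a manifest
  replays the run bit-identically.

## Known limitations

- The correlation rule table is order-sensitive by construction; results
  are deterministic but can change if the column order changes.
- The distance term dominates MRMD ranking at large sample counts (see
  above); the accuracy-driven truncation largely compensates, but subset
  composition varies between seeds on weakly separated data.
- Pruning, ranking and selection see the full labeled dataset before the
  final cross-validation (the pipeline's stage order); the independent fold
  seeds limit, but do not eliminate, selection feedback. The null-data test
  (δ = 0 at chance accuracy) bounds its practical effect.
- Reported Sn/Sp/ACC on small datasets carry binomial noise of a few
  percentage points; compare runs only at matched seeds and sizes.
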