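"""Walk the three reduction stages on a small synthetic dataset.

Prints the column count after each stage: min-max normalization leaves the
width unchanged, correlation pruning removes one member of every highly
correlated pair (|rho| > 0.85), MRMD keeps the smallest top-k subset that
maximizes cross-validated accuracy, and PCA truncates at 95% cumulative
eigenvalue contribution.
"""

from thermoraac import (
    GeneratorSpec,
    correlation_prune,
    extract_features,
    generate,
    mrmd_rank,
    mrmd_select,
    normalize,
    pca_fit,
    pca_transform,
)

dataset = generate(GeneratorSpec(n_pos=40, n_neg=40, length_range=(80, 200), seed=5))
fm = extract_features(dataset)
print(f"extracted : {fm.n_samples} x {fm.n_features}")

fm = normalize(fm)
prune = correlation_prune(fm, threshold=0.85)
fm = fm.drop_features(prune.removed)
print(f"pruned    : {fm.n_features} columns "
      f"(removed {len(prune.removed)}, reserved {len(prune.reserved)})")

ranking = mrmd_rank(fm)
print("top 5 by MR + MD:")
for score in ranking[:5]:
    print(f"  {score.name:28s} MR={score.relevance:.3f} MD={score.distance:.3f}")

selection = mrmd_select(ranking, fm, folds=5, seed=0, patience=10)
fm = fm.select_features(selection.feature_names)
print(f"selected  : top {selection.k} features "
      f"(CV accuracy {selection.accuracy:.1f}%)")

pca = pca_fit(fm, t_prime=0.95)
components = pca_transform(pca, fm)
print(f"projected : {components.shape[1]} components "
      f"(cumulative contribution {pca.cumulative_contribution:.3f})")
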