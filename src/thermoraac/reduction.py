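"""Three-stage dimensionality reduction.

1. Min-max normalization of every column to [0, 1], then rule-based
   correlation pruning: unordered column pairs are scanned in canonical
   order (upper triangle, row-major) and every pair whose |Pearson ρ|
   exceeds a threshold T feeds a removed set D and a reserved set R through
   a fixed rule table (see :func:`correlation_prune`).
2. MRMD ranking — each feature is scored by the sum of its relevance
   (|Pearson correlation with the class vector|) and its distance (mean
   Euclidean distance to all other feature columns) — followed by
   accuracy-driven truncation: cross-validated accuracy of a classifier on
   the top-k features is traced over k and the smallest k attaining the
   maximum observed accuracy is kept.
3. PCA on the retained columns, truncated at the smallest component count
   whose cumulative eigenvalue contribution reaches a threshold T'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .matrix import FeatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization and correlation


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize every column to [0, 1].

    Non-constant columns are mapped by (x − x_min)/(x_max − x_min);
    constant columns become all-zeros with a logged warning.
    """
    X = matrix.values
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        logger.warning(
            "%d constant column(s) normalized to zeros", int(constant.sum())
        )
    safe = np.where(constant, 1.0, span)
    out = (X - lo) / safe
    out[:, constant] = 0.0
    return FeatureMatrix(
        out, list(matrix.meta), list(matrix.ids),
        None if matrix.labels is None else matrix.labels.copy(),
        normalized=True,
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation (n − 1 convention).

    Returns 0 by convention (with a logged warning) when either vector has
    zero variance; raises on length mismatch or n < 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError("pearson requires n >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.dot(dx, dx) / (n - 1))
    sy = np.sqrt(np.dot(dy, dy) / (n - 1))
    if sx == 0.0 or sy == 0.0:
        logger.warning("zero-variance vector in pearson; returning 0 by convention")
        return 0.0
    return float(np.dot(dx, dy) / ((n - 1) * sx * sy))


def correlation_matrix(X: np.ndarray) -> np.ndarray:
    """Column-wise Pearson matrix; zero-variance columns correlate 0 with everything."""
    sd = X.std(axis=0)
    ok = sd > 0
    corr = np.zeros((X.shape[1], X.shape[1]))
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = sub
    elif ok.sum() == 1:
        corr[np.ix_(ok, ok)] = 1.0
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class PruneResult:
    """Outcome of rule-based correlation pruning.

    ``removed`` (D) and ``reserved`` (R) partition the features that took
    part in at least one high-correlation pair; features in neither set were
    never involved and are implicitly kept. ``driving_pairs`` lists every
    (X, Y, ρ) with |ρ| > threshold, in processing order.
    """

    removed: set[str]
    reserved: set[str]
    threshold: float
    driving_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    strict: bool = False

    def __post_init__(self) -> None:
        if self.removed & self.reserved:
            raise ValueError("removed and reserved sets must be disjoint")


def correlation_prune(
    matrix: FeatureMatrix, threshold: float = 0.85, strict: bool = False
) -> PruneResult:
    """Assign highly correlated features to removed (D) / reserved (R) sets.

    Unordered pairs (X, Y) — X the earlier column — are processed in
    canonical upper-triangle, row-major order. For each pair with
    |ρ(X, Y)| > threshold the first matching rule fires:

    1. X and Y both unassigned  → X ∈ R, Y ∈ D
    2. X unassigned, Y ∈ D      → X ∈ R
    3. X unassigned, Y ∈ R      → X ∈ D
    4. X ∈ R, Y unassigned      → Y ∈ D
    5. X ∈ D, Y unassigned      → Y ∈ D

    Pairs whose members are both already assigned are recorded but trigger
    no rule. With ``strict=True`` an extra pass moves the later-ordered
    member of any high pair whose members are both still retained into D,
    guaranteeing that no two retained features exceed the threshold.
    """
    if not matrix.normalized:
        raise ValueError("correlation_prune requires a normalized matrix")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    names = matrix.feature_names
    corr = correlation_matrix(matrix.values)

    removed: set[str] = set()
    reserved: set[str] = set()
    pairs: list[tuple[str, str, float]] = []
    hi, hj = np.nonzero(np.triu(np.abs(corr) > threshold, k=1))
    for i, j in zip(hi.tolist(), hj.tolist()):  # already row-major
        X, Y, rho = names[i], names[j], float(corr[i, j])
        pairs.append((X, Y, rho))
        x_free = X not in removed and X not in reserved
        y_free = Y not in removed and Y not in reserved
        if x_free and y_free:
            reserved.add(X)
            removed.add(Y)
        elif x_free and Y in removed:
            reserved.add(X)
        elif x_free and Y in reserved:
            removed.add(X)
        elif X in reserved and y_free:
            removed.add(Y)
        elif X in removed and y_free:
            removed.add(Y)
        # both already assigned: recorded, no rule fires

    if strict:
        for X, Y, _rho in pairs:
            if X not in removed and Y not in removed:
                removed.add(Y)
                reserved.discard(Y)
                reserved.add(X)

    return PruneResult(removed, reserved, threshold, pairs, strict)


# ---------------------------------------------------------------------------
# MRMD ranking and accuracy-driven truncation


@dataclass(frozen=True)
class MRMDScore:
    """Per-feature MRMD score: relevance MR, distance MD, and their sum."""

    name: str
    relevance: float
    distance: float

    @property
    def total(self) -> float:
        return self.relevance + self.distance


def mrmd_rank(matrix: FeatureMatrix) -> list[MRMDScore]:
    """Rank features by MR + MD, descending (ties broken by name, ascending).

    MR_i = |Pearson(F_i, class vector)| ∈ [0, 1]; MD_i = mean Euclidean
    distance from column i to every other column. Requires labels and at
    least two features (MD is undefined for a single feature).
    """
    if matrix.labels is None:
        raise ValueError("mrmd_rank requires labels")
    X = matrix.values
    n, m = X.shape
    if m < 2:
        raise ValueError("mrmd_rank requires at least 2 features")
    y = matrix.labels.astype(float)

    dy = y - y.mean()
    sy = dy.std()
    dX = X - X.mean(axis=0)
    sX = dX.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mr = np.abs((dX.T @ dy) / n / np.where(sX * sy == 0, np.inf, sX * sy))
    mr = np.where((sX == 0) | (sy == 0), 0.0, mr)

    dist = squareform(pdist(X.T, metric="euclidean"))
    md = dist.sum(axis=1) / (m - 1)

    scores = [
        MRMDScore(name, float(mr[i]), float(md[i]))
        for i, name in enumerate(matrix.feature_names)
    ]
    return sorted(scores, key=lambda s: (-s.total, s.name))


class SelectionError(RuntimeError):
    """Evaluator failure during subset search; carries the partial trace."""

    def __init__(self, message: str, trace: list[tuple[int, float]]):
        super().__init__(message)
        self.trace = trace


@dataclass
class SelectionResult:
    """Chosen subset size, its feature names, and the full (k, ACC%) trace."""

    k: int
    feature_names: list[str]
    trace: list[tuple[int, float]]

    @property
    def accuracy(self) -> float:
        return dict(self.trace)[self.k]


def mrmd_select(
    ranked: list[MRMDScore],
    matrix: FeatureMatrix,
    model: str = "svm",
    folds: int = 10,
    seed: int = 0,
    patience: Optional[int] = None,
) -> SelectionResult:
    """Truncate an MRMD ranking at the subset size maximizing CV accuracy.

    Evaluates cross-validated accuracy of ``model`` on the top-k ranked
    features for k = 1..M (full sweep) or until ``patience`` consecutive
    non-improving steps (early stop); returns the smallest k attaining the
    maximum observed accuracy.
    """
    from .evaluation import make_classifier  # local import to avoid a cycle

    names = [s.name for s in ranked]
    missing = set(names) - set(matrix.feature_names)
    if missing:
        raise ValueError(f"ranking covers unknown features: {sorted(missing)}")
    if matrix.labels is None:
        raise ValueError("mrmd_select requires labels")
    ordered = matrix.select_features(names)
    X, y = ordered.values, ordered.labels
    m = X.shape[1]

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    trace: list[tuple[int, float]] = []
    best_acc = -np.inf
    best_k = 1
    since_best = 0
    for k in range(1, m + 1):
        try:
            acc = float(
                cross_val_score(
                    make_classifier(model, seed), X[:, :k], y,
                    cv=cv, scoring="accuracy",
                ).mean() * 100.0
            )
        except Exception as exc:  # noqa: BLE001 - surfaced with partial trace
            raise SelectionError(f"evaluator failed at k={k}: {exc}", trace) from exc
        trace.append((k, acc))
        if acc > best_acc:
            best_acc, best_k, since_best = acc, k, 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                logger.info("selection stopped at k=%d (patience %d)", k, patience)
                break
    return SelectionResult(best_k, names[:best_k], trace)


# ---------------------------------------------------------------------------
# PCA truncated by cumulative contribution


@dataclass
class PCAModel:
    """Centered PCA with components truncated by cumulative contribution.

    ``components`` holds the k retained axes as rows; ``eigenvalues`` are
    all sample covariance eigenvalues (non-increasing). The sign convention
    fixes each axis's largest-magnitude loading to be positive.
    """

    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    k: int
    t_prime: float
    cumulative_contribution: float


def choose_k(eigenvalues: np.ndarray, t_prime: float) -> int:
    """Smallest k whose cumulative eigenvalue share reaches ``t_prime``."""
    if not (0.0 < t_prime <= 1.0):
        raise ValueError("t_prime must be in (0, 1]")
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        raise ValueError("eigenvalues must have positive total")
    shares = np.cumsum(ev) / total
    return int(np.searchsorted(shares, t_prime - 1e-12) + 1)


def pca_fit(
    matrix: FeatureMatrix | np.ndarray,
    t_prime: float = 0.95,
    k_override: Optional[int] = None,
) -> PCAModel:
    """Fit PCA by SVD of the column-centered data.

    Components are retained up to the smallest k whose cumulative eigenvalue
    contribution reaches ``t_prime``, unless ``k_override`` fixes k directly
    (error if it exceeds the data rank).
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    n, m = X.shape
    if n < 2:
        raise ValueError("pca_fit requires at least 2 rows")
    mean = X.mean(axis=0)
    centered = X - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    tol = s.max() * max(n, m) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if k_override is not None:
        if k_override < 1 or k_override > rank:
            raise ValueError(f"k_override {k_override} exceeds data rank {rank}")
        k = k_override
    else:
        k = min(choose_k(eigenvalues[:rank], t_prime), rank)

    components = vt[:k].copy()
    for row in components:  # deterministic sign: largest |loading| positive
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    total = eigenvalues.sum()
    return PCAModel(
        mean=mean,
        components=components,
        eigenvalues=eigenvalues,
        k=k,
        t_prime=t_prime,
        cumulative_contribution=float(eigenvalues[:k].sum() / total) if total > 0 else 1.0,
    )


def pca_transform(model: PCAModel, matrix: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Project data onto the model's retained axes (n x k component matrix)."""
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.mean.shape[0]})"
        )
    return (X - model.mean) @ model.components.T
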