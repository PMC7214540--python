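"""Classifier evaluation under stratified k-fold cross-validation.

Metrics follow the standard confusion-count definitions with the positive
class being thermophilic:

    Sn  = TP / (TP + FN) x 100%      (thermophilic recall)
    Sp  = TN / (TN + FP) x 100%      (non-thermophilic recall)
    ACC = (TP + TN) / (TP + TN + FP + FN) x 100%

Four classifier types are supported: an RBF-kernel support vector machine,
a random forest, a decision tree, and Gaussian naive Bayes, all at
near-default hyperparameters. ROC curves are computed from the models'
continuous scores on held-out observations, pooled across folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import FeatureMatrix

MODEL_NAMES = ("svm", "random_forest", "decision_tree", "naive_bayes")


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cell counts (positive = thermophilic)."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass(frozen=True)
class Metrics:
    """Sn/Sp/ACC percentages; Sn or Sp is None when its class is absent."""

    sn: Optional[float]
    sp: Optional[float]
    acc: float


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy (percentages) from cell counts.

    Sn (resp. Sp) is reported as None — not 0 — when there are no positive
    (resp. negative) observations; raises when all four cells are zero.
    """
    if counts.total == 0:
        raise ValueError("metrics undefined for all-zero confusion counts")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sn = counts.tp / pos * 100.0 if pos else None
    sp = counts.tn / neg * 100.0 if neg else None
    acc = (counts.tp + counts.tn) / counts.total * 100.0
    return Metrics(sn, sp, acc)


@dataclass
class ROCResult:
    """ROC points ordered from (0,0) to (1,1) with trapezoid-rule area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    area: float


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve from continuous scores (higher = more thermophilic-like).

    Tied scores collapse to a single threshold step; raises if only one
    class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCResult(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the four supported classifier types.

    Hyperparameters are near-default: RBF SVM with C = 1 and
    gamma = 1/n_features; 100-tree random forest; library-default decision
    tree and Gaussian naive Bayes.
    """
    if name == "svm":
        return SVC(C=1.0, kernel="rbf", gamma="auto", random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown model {name!r}; available: {MODEL_NAMES}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return np.asarray(model.predict_proba(X)[:, 1], dtype=float)


@dataclass
class EvalReport:
    """Cross-validation outcome for one classifier.

    Pooled metrics (primary) sum the per-fold confusion counts before
    applying the metric formulas; ``fold_acc_mean``/``fold_acc_sd`` give the
    secondary fold-averaged view. ROC points come from held-out scores
    pooled across folds.
    """

    model: str
    folds: int
    seed: int
    fold_counts: list[ConfusionCounts]
    pooled: ConfusionCounts
    sn: Optional[float]
    sp: Optional[float]
    acc: float
    fold_acc_mean: float
    fold_acc_sd: float
    roc: ROCResult

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "folds": self.folds,
            "seed": self.seed,
            "pooled_counts": {
                "tp": self.pooled.tp, "tn": self.pooled.tn,
                "fp": self.pooled.fp, "fn": self.pooled.fn,
            },
            "fold_counts": [
                {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                for c in self.fold_counts
            ],
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "fold_acc_mean": self.fold_acc_mean,
            "fold_acc_sd": self.fold_acc_sd,
            "roc_auc": self.roc.area,
            "roc_fpr": self.roc.fpr.tolist(),
            "roc_tpr": self.roc.tpr.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        sn = f"{self.sn:.2f}" if self.sn is not None else "n/a"
        sp = f"{self.sp:.2f}" if self.sp is not None else "n/a"
        return (
            f"{self.model}: {self.folds}-fold CV — "
            f"Sn {sn}%  Sp {sp}%  ACC {self.acc:.2f}% "
            f"(fold mean {self.fold_acc_mean:.2f} ± {self.fold_acc_sd:.2f})  "
            f"AUC {self.roc.area:.4f}"
        )


def plot_roc(reports: Sequence[EvalReport] | EvalReport, path: str | Path) -> None:
    """Plot one or more ROC curves to an image file (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(reports, EvalReport):
        reports = [reports]
    fig, ax = plt.subplots(figsize=(5, 5))
    for report in reports:
        ax.plot(report.roc.fpr, report.roc.tpr,
                label=f"{report.model} (AUC {report.roc.area:.3f})")
    ax.plot([0, 1], [0, 1], "k:", linewidth=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def crossval(
    matrix: FeatureMatrix | np.ndarray,
    labels: Optional[np.ndarray] = None,
    model: str = "svm",
    folds: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of one classifier.

    Fold assignment is stratified and deterministic per seed; the model is
    refit inside every training fold. Accepts a labeled
    :class:`FeatureMatrix` or a plain array plus label vector.
    """
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values
        y = matrix.labels if labels is None else np.asarray(labels, int)
    else:
        X = np.asarray(matrix, dtype=float)
        y = np.asarray(labels, dtype=int) if labels is not None else None
    if y is None:
        raise ValueError("crossval requires labels")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} observations, fewer than {folds} folds"
        )

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_counts: list[ConfusionCounts] = []
    all_scores = np.empty(len(y), dtype=float)
    for train, test in cv.split(X, y):
        clf = make_classifier(model, seed)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        fold_counts.append(ConfusionCounts.from_predictions(y[test], pred))
        all_scores[test] = _scores(clf, X[test])

    pooled = sum(fold_counts, ConfusionCounts())
    m = metrics(pooled)
    fold_accs = [metrics(c).acc for c in fold_counts]
    return EvalReport(
        model=model,
        folds=folds,
        seed=seed,
        fold_counts=fold_counts,
        pooled=pooled,
        sn=m.sn,
        sp=m.sp,
        acc=m.acc,
        fold_acc_mean=float(np.mean(fold_accs)),
        fold_acc_sd=float(np.std(fold_accs, ddof=1)),
        roc=roc_points(all_scores, y),
    )
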