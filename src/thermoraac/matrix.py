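"""The feature matrix container shared by extraction, reduction and evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

FAMILIES = ("physchem188", "dipeptide", "acc")


@dataclass(frozen=True)
class FeatureMeta:
    """Per-column descriptor: name, feature family, gap λ where applicable."""

    name: str
    family: str
    lam: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")


def meta_from_name(name: str) -> FeatureMeta:
    """Reconstruct column metadata from a canonical feature name."""
    if name.startswith("RD|"):
        return FeatureMeta(name, "dipeptide", lam=int(name.split("|")[1]))
    if name.startswith(("AC|", "CC|")):
        return FeatureMeta(name, "acc")
    return FeatureMeta(name, "physchem188")


@dataclass
class FeatureMatrix:
    """n_samples x n_features numeric matrix with column metadata and row labels."""

    values: np.ndarray
    meta: list[FeatureMeta]
    ids: list[str]
    labels: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, m = self.values.shape
        if len(self.meta) != m:
            raise ValueError(f"{len(self.meta)} meta entries for {m} columns")
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        names = [fm.name for fm in self.meta]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one per row")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [fm.name for fm in self.meta]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def drop_features(self, names: Iterable[str]) -> "FeatureMatrix":
        """A new matrix with the named columns removed (order preserved)."""
        drop = set(names)
        unknown = drop - set(self.feature_names)
        if unknown:
            raise KeyError(f"unknown features: {sorted(unknown)}")
        keep = [i for i, fm in enumerate(self.meta) if fm.name not in drop]
        return FeatureMatrix(
            self.values[:, keep],
            [self.meta[i] for i in keep],
            list(self.ids),
            None if self.labels is None else self.labels.copy(),
            self.normalized,
        )

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        """A new matrix with exactly the named columns, in the given order."""
        index = {fm.name: i for i, fm in enumerate(self.meta)}
        cols = [index[n] for n in names]
        return FeatureMatrix(
            self.values[:, cols],
            [self.meta[i] for i in cols],
            list(self.ids),
            None if self.labels is None else self.labels.copy(),
            self.normalized,
        )

    def to_csv(self, path: str | Path) -> None:
        """Serialize as CSV: columns ``id``, ``label``, then one per feature."""
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels if self.labels is not None else "")
        df.insert(0, "id", self.ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError("feature CSV must start with 'id' and 'label' columns")
        labels = None
        if not df["label"].isna().all():
            labels = df["label"].to_numpy(dtype=int)
        feature_cols = list(df.columns[2:])
        return cls(
            df[feature_cols].to_numpy(dtype=float),
            [meta_from_name(n) for n in feature_cols],
            df["id"].astype(str).tolist(),
            labels,
        )
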