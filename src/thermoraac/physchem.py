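"""Physicochemical sequence descriptors: the 188-dimensional block vector
and auto-cross covariance (ACC) features.

The 188D descriptor concatenates four blocks computed on the original
(unreduced) sequence:

* 20 amino acid frequencies (order ACDEFGHIKLMNPQRSTVWY);
* 24 = 8 properties x 3 groups: the fraction of residues falling in each
  group of a three-way physicochemical partition;
* 120 = 8 x 3 x 5: distribution — the normalized sequence positions of the
  first, 25%, 50%, 75% and 100% occurrences of each group (five zeros when
  the group is absent);
* 24 = 8 x 3: transition — counts of adjacent residue pairs that cross
  between two different groups (the three unordered cross-group types),
  divided by L − 1.

ACC features are lagged covariances of standardized numeric property traces
along the sequence: AC pairs a property with itself, CC pairs two different
properties. With N numeric scales and maximum lag lg the family contributes
N·lg + N·(N−1)·lg features (18 under the default N = 3, lg = 2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from itertools import permutations

import numpy as np

from .sequence_io import AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyPartition:
    """A three-way grouping of the 20 amino acids under one property."""

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError(f"property {self.name!r}: exactly 3 groups required")
        letters = "".join(self.groups)
        if len(letters) != 20 or set(letters) != set(AMINO_ACIDS):
            raise ValueError(
                f"property {self.name!r}: groups must partition the 20 amino acids"
            )

    def group_codes(self) -> dict[str, int]:
        return {aa: gi for gi, group in enumerate(self.groups) for aa in group}


@dataclass(frozen=True)
class PropertyScale:
    """A numeric per-residue scale, standardized over the 20 amino acids."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(f"scale {self.name!r} must cover the 20 amino acids")

    def standardized(self) -> dict[str, float]:
        """Zero-mean, unit-variance transform over the 20 amino acids."""
        raw = np.array([self.values[aa] for aa in AMINO_ACIDS])
        z = (raw - raw.mean()) / raw.std()
        return dict(zip(AMINO_ACIDS, z))


def _data_text(filename: str) -> str:
    return resources.files("thermoraac.data").joinpath(filename).read_text()


@lru_cache(maxsize=None)
def default_partitions() -> tuple[PropertyPartition, ...]:
    """The 8 bundled property partitions (conventional 3-group CTD splits)."""
    rows = [line.split("\t") for line in _data_text("ctd_groups.tsv").strip().splitlines()]
    header, body = rows[0], rows[1:]
    assert header == ["property", "group1", "group2", "group3"]
    return tuple(
        PropertyPartition(name, (g1, g2, g3)) for name, g1, g2, g3 in body
    )


@lru_cache(maxsize=None)
def default_scales() -> tuple[PropertyScale, ...]:
    """The 3 bundled numeric scales (hydrophobicity, hydrophilicity, side-chain mass)."""
    rows = [line.split("\t") for line in _data_text("acc_scales.tsv").strip().splitlines()]
    header, body = rows[0], rows[1:]
    names = header[1:]
    columns: dict[str, dict[str, float]] = {n: {} for n in names}
    for row in body:
        aa = row[0]
        for n, v in zip(names, row[1:]):
            columns[n][aa] = float(v)
    return tuple(PropertyScale(n, columns[n]) for n in names)


# ---------------------------------------------------------------------------
# 188D descriptor


def physchem188_names(
    partitions: tuple[PropertyPartition, ...] | None = None,
) -> tuple[str, ...]:
    parts = partitions or default_partitions()
    names = [f"AAC|{aa}" for aa in AMINO_ACIDS]
    names += [f"CTDC|{p.name}|G{g + 1}" for p in parts for g in range(3)]
    names += [
        f"CTDD|{p.name}|G{g + 1}|{q}"
        for p in parts
        for g in range(3)
        for q in ("first", "p25", "p50", "p75", "p100")
    ]
    names += [
        f"CTDT|{p.name}|{pair}"
        for p in parts
        for pair in ("G1G2", "G1G3", "G2G3")
    ]
    return tuple(names)


def _distribution(positions: np.ndarray, length: int) -> list[float]:
    """Normalized positions of the 1st / 25% / 50% / 75% / 100% occurrences."""
    n = len(positions)
    if n == 0:
        return [0.0] * 5
    out = [float(positions[0] + 1) / length]
    for frac in (0.25, 0.50, 0.75, 1.00):
        idx = max(math.ceil(frac * n), 1) - 1
        out.append(float(positions[idx] + 1) / length)
    return out


def physchem188(
    record: ProteinRecord | str,
    partitions: tuple[PropertyPartition, ...] | None = None,
) -> np.ndarray:
    """Compute the 188-dimensional physicochemical descriptor of a sequence.

    Works on the original (unreduced) sequence. For a length-1 sequence the
    transition block is all zeros (no adjacent pairs) with a logged warning.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    parts = partitions or default_partitions()
    L = len(seq)
    if L < 1:
        raise ValueError("empty sequence")
    if L < 2:
        logger.warning("length-1 sequence: transition block is all zeros")

    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    codes = np.fromiter((aa_index[ch] for ch in seq), dtype=np.int64, count=L)

    aac = np.bincount(codes, minlength=20) / L

    composition: list[float] = []
    distribution: list[float] = []
    transition: list[float] = []
    for part in parts:
        gmap = np.empty(20, dtype=np.int64)
        for aa, gi in part.group_codes().items():
            gmap[aa_index[aa]] = gi
        gseq = gmap[codes]
        gcounts = np.bincount(gseq, minlength=3)
        composition.extend(gcounts / L)
        for g in range(3):
            distribution.extend(_distribution(np.flatnonzero(gseq == g), L))
        if L >= 2:
            a, b = gseq[:-1], gseq[1:]
            lo, hi = np.minimum(a, b), np.maximum(a, b)
            for g1, g2 in ((0, 1), (0, 2), (1, 2)):
                transition.append(float(np.sum((lo == g1) & (hi == g2))) / (L - 1))
        else:
            transition.extend([0.0, 0.0, 0.0])

    vec = np.concatenate([aac, composition, distribution, transition])
    assert vec.size == 20 + len(parts) * (3 + 15 + 3)
    return vec


# ---------------------------------------------------------------------------
# Auto-cross covariance


@dataclass(frozen=True)
class ACCConfig:
    """ACC configuration: maximum lag and the numeric property scales."""

    lg: int = 2
    scales: tuple[PropertyScale, ...] = ()

    def __post_init__(self) -> None:
        if self.lg < 1:
            raise ValueError("lg must be >= 1")
        if not self.scales:
            object.__setattr__(self, "scales", default_scales())

    @property
    def n_features(self) -> int:
        n = len(self.scales)
        return n * self.lg + n * (n - 1) * self.lg


def lagged_covariance(x: np.ndarray, y: np.ndarray, lag: int) -> float:
    """Covariance of two equal-length traces at a positive lag.

    Each trace is centered on its own sequence mean; the sum over the
    L − lag overlapping positions is divided by L − lag. With ``x is y``
    this is the autocovariance term AC(i, lag).
    """
    L = len(x)
    if len(y) != L:
        raise ValueError("traces must have equal length")
    if lag < 1 or lag >= L:
        raise ValueError(f"lag must be in 1..L-1, got {lag} for length {L}")
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.dot(dx[: L - lag], dy[lag:]) / (L - lag))


def acc_names(config: ACCConfig | None = None) -> tuple[str, ...]:
    cfg = config or ACCConfig()
    names = [
        f"AC|{s.name}|{g}" for s in cfg.scales for g in range(1, cfg.lg + 1)
    ]
    names += [
        f"CC|{s1.name}|{s2.name}|{g}"
        for s1, s2 in permutations(cfg.scales, 2)
        for g in range(1, cfg.lg + 1)
    ]
    return tuple(names)


def acc_features(
    record: ProteinRecord | str, config: ACCConfig | None = None
) -> np.ndarray:
    """Auto-cross covariance features of a sequence.

    Column order: all AC terms (scale-major, lag-minor), then all CC terms
    over ordered scale pairs (pair-major, lag-minor). Raises for sequences
    with L <= lg (no overlapping positions at the largest lag).
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    cfg = config or ACCConfig()
    L = len(seq)
    if L <= cfg.lg:
        raise ValueError(f"sequence too short for lag {cfg.lg} (length {L})")

    traces = []
    for scale in cfg.scales:
        z = scale.standardized()
        traces.append(np.fromiter((z[ch] for ch in seq), dtype=float, count=L))

    out = []
    for trace in traces:
        for g in range(1, cfg.lg + 1):
            out.append(lagged_covariance(trace, trace, g))
    for t1, t2 in permutations(traces, 2):
        for g in range(1, cfg.lg + 1):
            out.append(lagged_covariance(t1, t2, g))
    return np.array(out)
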