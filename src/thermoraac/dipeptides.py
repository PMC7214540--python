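"""Gapped dipeptide composition over a (possibly reduced) amino acid alphabet.

A λ-gap dipeptide is an ordered symbol pair separated by λ intervening
positions: λ = 0 is an adjacent pair (written AA), λ = 1 is A*A, λ = 2 is
A**A. For a sequence of length L there are max(L − 1 − λ, 0) countable pairs
at gap λ, and the frequency of dipeptide type j is its count divided by the
per-gap total:

    f_λ(j) = y_λ(j) / Σ_j y_λ(j)

so each gap block of k² frequencies sums to 1 whenever the sequence is long
enough to contain at least one pair at that gap. Over the 19-symbol reduced
alphabet this yields 361 feature slots per gap (1083 for λ ∈ {0, 1, 2});
over the original alphabet, 400 per gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import ReductionScheme, builtin_scheme
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class DipeptideFeatureSet:
    """Gapped dipeptide counts and frequencies for one sequence.

    ``values`` and ``counts`` have length k²·(max_gap+1), ordered gap-major:
    gap ascending, then first symbol, then second symbol, both in the
    scheme's declared group order. ``countable[lam]`` is False when the
    sequence is too short to contain any pair at that gap (its block is all
    zeros rather than 0/0).
    """

    scheme: ReductionScheme
    max_gap: int
    values: np.ndarray
    counts: np.ndarray
    countable: tuple[bool, ...]
    names: tuple[str, ...]

    def block(self, lam: int) -> np.ndarray:
        """The k² frequency block at gap ``lam``."""
        k2 = self.scheme.k**2
        return self.values[lam * k2 : (lam + 1) * k2]


def feature_names(scheme: ReductionScheme, max_gap: int) -> tuple[str, ...]:
    """Column names ``RD|λ|a|b`` in the canonical gap-major order."""
    reps = scheme.representatives
    return tuple(
        f"RD|{lam}|{a}|{b}"
        for lam in range(max_gap + 1)
        for a in reps
        for b in reps
    )


def gapped_dipeptide_features(
    sequence: str, scheme: ReductionScheme, max_gap: int = 2
) -> DipeptideFeatureSet:
    """Count and normalize λ-gap dipeptides of a reduced sequence.

    Parameters
    ----------
    sequence : str
        A sequence over the scheme's representative symbols (i.e. already
        recoded by :func:`~thermoraac.alphabet.reduce_sequence`, or any
        sequence when the scheme is ``identity20``).
    scheme : ReductionScheme
        Defines the k-symbol alphabet and the column order.
    max_gap : int
        Largest gap λ; blocks are computed for every λ in 0..max_gap.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    reps = scheme.representatives
    k = scheme.k
    index = {sym: i for i, sym in enumerate(reps)}
    bad = set(sequence) - set(index)
    if bad:
        raise ValueError(
            f"symbols {sorted(bad)} are not representatives of scheme {scheme.name!r}"
        )
    codes = np.fromiter((index[ch] for ch in sequence), dtype=np.int64, count=len(sequence))
    L = len(codes)

    counts = np.zeros((max_gap + 1) * k * k, dtype=np.int64)
    values = np.zeros_like(counts, dtype=float)
    countable = []
    for lam in range(max_gap + 1):
        n_pairs = L - 1 - lam
        block = counts[lam * k * k : (lam + 1) * k * k]
        if n_pairs <= 0:
            countable.append(False)
            logger.warning(
                "sequence of length %d has no countable pairs at gap %d; zero block",
                L, lam,
            )
            continue
        countable.append(True)
        first = codes[: L - 1 - lam]
        second = codes[1 + lam :]
        np.add.at(block, first * k + second, 1)
        values[lam * k * k : (lam + 1) * k * k] = block / n_pairs

    return DipeptideFeatureSet(
        scheme=scheme,
        max_gap=max_gap,
        values=values,
        counts=counts,
        countable=tuple(countable),
        names=feature_names(scheme, max_gap),
    )


def original_dipeptide_features(
    record: ProteinRecord | str, max_gap: int = 2
) -> DipeptideFeatureSet:
    """Gapped dipeptide features over the original 20-letter alphabet.

    Identical to :func:`gapped_dipeptide_features` with the ``identity20``
    scheme (400 types per gap); used for the unreduced-dipeptide ablation.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    return gapped_dipeptide_features(seq, builtin_scheme("identity20"), max_gap)
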