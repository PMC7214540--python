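"""Reading, validating and subsampling labeled protein sequence data.

Sequences are restricted to the 20 standard amino acids; descriptors
downstream are defined only over that alphabet, so validation is strict by
default. The binary label convention is fixed throughout the package:
thermophilic = 1 = positive, non-thermophilic = 0 = negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, in the canonical alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residue codes that are never accepted, under any policy.
_ALWAYS_REJECTED = frozenset("*-")


class SequenceValidationError(ValueError):
    """A sequence contains a residue outside the 20-letter alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein observation: identifier, validated sequence, optional label.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within a dataset.
    sequence : str
        Uppercase string over ``ACDEFGHIKLMNPQRSTVWY``, length >= 1.
    label : int or None
        1 for thermophilic (positive), 0 for non-thermophilic, None if
        unlabeled.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """An ordered collection of labeled protein records."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def positive_count(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def negative_count(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    @property
    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        if any(r.label is None for r in self.records):
            raise ValueError("dataset contains unlabeled records")
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def validate_sequence(sequence: str, record_id: str) -> str:
    """Uppercase and validate a raw sequence string.

    Raises :class:`SequenceValidationError` naming the record and the first
    offending character if any residue falls outside the 20-letter alphabet.
    """
    seq = sequence.upper()
    for ch in seq:
        if ch not in _AA_SET:
            raise SequenceValidationError(
                f"record {record_id!r}: invalid residue {ch!r} "
                "(only the 20 standard amino acids are accepted)"
            )
    return seq


def read_fasta(
    path: str | Path,
    label: Optional[int] = None,
    policy: str = "strict",
) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path : path
        FASTA file ('>' headers, multi-line bodies concatenated).
    label : int, optional
        If given, applied to every record (1 = thermophilic).
    policy : {"strict", "drop-record"}
        How to treat sequences with non-standard residues (B, J, O, U, X, Z,
        and anything else outside the 20-letter alphabet): "strict" raises,
        "drop-record" skips the record with a logged warning. '*' and '-'
        are always rejected.
    """
    if policy not in ("strict", "drop-record"):
        raise ValueError(f"unknown residue policy {policy!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise ValueError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        raw = str(entry.seq)
        if any(ch in _ALWAYS_REJECTED for ch in raw):
            bad = next(ch for ch in raw if ch in _ALWAYS_REJECTED)
            raise SequenceValidationError(
                f"record {rid!r}: residue {bad!r} is never accepted"
            )
        try:
            seq = validate_sequence(raw, rid)
        except SequenceValidationError:
            if policy == "drop-record":
                logger.warning("dropping record %r (non-standard residue)", rid)
                continue
            raise
        records.append(ProteinRecord(id=rid, sequence=seq, label=label))
    if not records and not seen:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping, round-trip safe)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write the two-column label TSV (``id<TAB>{0,1}``) with a header line."""
    lines = ["id\tlabel"]
    for rec in records:
        if rec.label is None:
            raise ValueError(f"record {rec.id!r} is unlabeled")
        lines.append(f"{rec.id}\t{rec.label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``id<TAB>{0,1}``; one header line is allowed."""
    labels: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno + 1}: expected two tab-separated columns")
            rid, value = parts
            if value not in ("0", "1"):
                if lineno == 0:  # header line
                    continue
                raise ValueError(f"{path}:{lineno + 1}: label must be 0 or 1, got {value!r}")
            if rid in labels:
                raise ValueError(f"{path}:{lineno + 1}: duplicate id {rid!r}")
            labels[rid] = int(value)
    return labels


def apply_labels(records: Sequence[ProteinRecord], labels: dict[str, int]) -> LabeledDataset:
    """Attach labels from a label map to records, by id."""
    out = []
    for rec in records:
        if rec.id not in labels:
            raise ValueError(f"no label for record {rec.id!r}")
        out.append(ProteinRecord(rec.id, rec.sequence, labels[rec.id]))
    return LabeledDataset(out)


def sample_balanced(dataset: LabeledDataset, n_per_class: int, seed: int) -> LabeledDataset:
    """Draw a class-balanced subsample without replacement.

    Exactly ``n_per_class`` records per class, deterministic for a fixed
    seed, preserving the relative input order within the sample. This is the
    convention used to build a balanced training set from an imbalanced
    labeled collection (e.g. 500 + 500 from 915 + 793).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    keep: set[int] = set()
    for cls in (1, 0):
        idx = [i for i, r in enumerate(dataset.records) if r.label == cls]
        if len(idx) < n_per_class:
            raise ValueError(
                f"class {cls} has only {len(idx)} records, need {n_per_class}"
            )
        chosen = rng.choice(len(idx), size=n_per_class, replace=False)
        keep.update(idx[i] for i in chosen)
    return LabeledDataset([dataset.records[i] for i in sorted(keep)])
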