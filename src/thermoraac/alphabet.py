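"""Reduced amino acid alphabets.

A reduction scheme partitions the 20 standard amino acids into k disjoint
groups and recodes a sequence by replacing every residue with its group's
representative symbol. The default scheme merges Ile and Val into a single
class represented by V (a 19-symbol alphabet derived from substitution-model
clustering); the classic 6-class Dayhoff grouping and the identity map are
also built in, and custom schemes can be loaded from a plain-text file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .sequence_io import AMINO_ACIDS, ProteinRecord

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ReductionScheme:
    """A named partition of the 20 amino acids with one representative per group."""

    name: str
    groups: tuple[str, ...]
    representatives: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.representatives):
            raise ValueError("one representative required per group")
        letters = "".join(self.groups)
        if len(letters) != len(set(letters)):
            raise ValueError(f"scheme {self.name!r}: groups are not disjoint")
        if set(letters) != _AA_SET:
            missing = _AA_SET - set(letters)
            extra = set(letters) - _AA_SET
            raise ValueError(
                f"scheme {self.name!r}: groups must cover exactly the 20 amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for group, rep in zip(self.groups, self.representatives):
            if rep not in group:
                raise ValueError(
                    f"scheme {self.name!r}: representative {rep!r} not in group {group!r}"
                )
        if len(set(self.representatives)) != len(self.representatives):
            raise ValueError(f"scheme {self.name!r}: representatives not distinct")

    @property
    def k(self) -> int:
        """Number of groups (the reduced alphabet size)."""
        return len(self.groups)

    @property
    def mapping(self) -> dict[str, str]:
        """Residue -> representative map."""
        return {
            aa: rep
            for group, rep in zip(self.groups, self.representatives)
            for aa in group
        }

    def translation_table(self) -> dict[int, int]:
        return str.maketrans({aa: rep for aa, rep in self.mapping.items()})


def _first_letter_reps(groups: tuple[str, ...]) -> tuple[str, ...]:
    return tuple(g[0] for g in groups)


# 19-class scheme: Ile and Val merged (representative V); all other classes
# are singletons. Declared group order fixes the feature column order.
_SUSKO19_GROUPS = (
    "A", "C", "D", "E", "F", "G", "H", "IV", "K", "L",
    "M", "N", "P", "Q", "R", "S", "T", "W", "Y",
)
_SUSKO19_REPS = (
    "A", "C", "D", "E", "F", "G", "H", "V", "K", "L",
    "M", "N", "P", "Q", "R", "S", "T", "W", "Y",
)

_DAYHOFF6_GROUPS = ("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C")

_BUILTINS = {
    "susko19": ReductionScheme("susko19", _SUSKO19_GROUPS, _SUSKO19_REPS),
    "dayhoff6": ReductionScheme(
        "dayhoff6", _DAYHOFF6_GROUPS, _first_letter_reps(_DAYHOFF6_GROUPS)
    ),
    "identity20": ReductionScheme(
        "identity20", tuple(AMINO_ACIDS), tuple(AMINO_ACIDS)
    ),
}


def builtin_scheme(name: str) -> ReductionScheme:
    """Return a built-in reduction scheme by name.

    Available: ``susko19`` (19 classes, I/V merged, representative V),
    ``dayhoff6`` (AGPST | DENQ | HKR | ILMV | FWY | C, first-letter
    representatives), ``identity20`` (no reduction).
    """
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; available: {sorted(_BUILTINS)}"
        ) from None


def load_scheme(path: str | Path, name: str | None = None) -> ReductionScheme:
    """Load a custom scheme from a text file, one group per line (e.g. ``AGPST``).

    The first letter of each line is the group's representative. Lines must
    jointly partition the 20-letter alphabet.
    """
    groups = tuple(
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    )
    return ReductionScheme(name or Path(path).stem, groups, _first_letter_reps(groups))


def reduce_sequence(record: ProteinRecord | str, scheme: ReductionScheme) -> str:
    """Recode a sequence onto the scheme's representative alphabet.

    Length is preserved; each residue is replaced by its group representative.
    """
    seq = record.sequence if isinstance(record, ProteinRecord) else record
    mapping = scheme.mapping
    missing = set(seq) - set(mapping)
    if missing:
        raise ValueError(
            f"residues {sorted(missing)} not covered by scheme {scheme.name!r}"
        )
    return seq.translate(scheme.translation_table())
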