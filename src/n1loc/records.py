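"""Core domain types: protein records, localization classes, alignment sets.

The residue alphabet is fixed at 21 symbols: the 20 standard amino acids
plus ``X`` for any nonstandard or ambiguous residue.  Encodings that track
gaps use a 22nd symbol ``-``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: 20 standard amino acids (alphabetical) followed by 'X'; index order is frozen.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = "-"
#: Column index of the gap symbol in 22-wide profile encodings.
GAP_INDEX = len(ALPHABET)

#: Ambiguity / nonstandard residue codes collapsed to 'X' on input.
_NONSTANDARD = set("BZJUO*")


class LocalizationClass(enum.IntEnum):
    """The eight subcellular localization classes.

    The integer index order is frozen: it defines output-unit order in the
    network, column order in prediction files, and argmax tie-breaking
    (lowest index wins).
    """

    Other = 0
    Cytoplasm = 1
    GolgiApparatus = 2
    Membrane = 3
    Mitochondrion = 4
    Nucleus = 5
    Plastid = 6
    Secreted = 7

    @classmethod
    def parse(cls, token: str) -> "LocalizationClass":
        """Parse a class name, case-insensitive, spaces/underscores interchangeable.

        Raises ``ValueError`` for tokens that are not one of the 8 names.
        """
        key = token.strip().lower().replace(" ", "").replace("_", "")
        try:
            return _CLASS_LOOKUP[key]
        except KeyError:
            raise ValueError(
                f"unknown localization class {token!r}; expected one of "
                + ", ".join(c.name for c in cls)
            ) from None


_CLASS_LOOKUP = {c.name.lower(): c for c in LocalizationClass}

N_CLASSES = len(LocalizationClass)


def sanitize_sequence(seq: str) -> str:
    """Uppercase a residue string and collapse nonstandard codes to 'X'.

    Raises ``ValueError`` on characters that are not amino-acid letters.
    """
    out = []
    for ch in seq.upper():
        if ch in ALPHABET_INDEX:
            out.append(ch)
        elif ch in _NONSTANDARD:
            out.append("X")
        elif ch.isalpha():
            # unknown letters are ambiguity by definition
            out.append("X")
        else:
            raise ValueError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, sanitized residue string, optional class label."""

    id: str
    sequence: str
    label: Optional[LocalizationClass] = None

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside the 21-letter "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentSet:
    """A multiple sequence alignment for one query.

    Row 0 is the query itself.  All rows have equal length over the
    21-letter alphabet plus the gap symbol.
    """

    query_id: str
    rows: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        rows = tuple(self.rows)
        object.__setattr__(self, "rows", rows)
        if len(rows) < 1:
            raise ValueError(f"alignment for {self.query_id!r} has no rows")
        width = len(rows[0])
        for i, row in enumerate(rows):
            if len(row) != width:
                raise ValueError(
                    f"alignment for {self.query_id!r} is ragged: row {i} has "
                    f"length {len(row)}, expected {width}"
                )
            bad = set(row) - set(ALPHABET) - {GAP}
            if bad:
                raise ValueError(
                    f"alignment row {i} for {self.query_id!r} has invalid "
                    f"symbols: {sorted(bad)}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])
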