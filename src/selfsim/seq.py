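"""Core sequence containers and reduced-alphabet encodings.

rRNA chains are modelled as strings over ``{A, U, G, C, N}`` where ``N``
stands for a reconstructed alignment gap.  Coordinates are 1-based with
inclusive ends everywhere a user sees them; 0-based half-open intervals
appear only at internal boundaries and never in files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

RNA_ALPHABET = frozenset("AUGCN")

#: purine/pyrimidine (RY) coarsening; transitions (A<->G, U<->C) are invisible
RY_MAP = str.maketrans({"A": "R", "G": "R", "U": "Y", "C": "Y"})


class Molecule(str, Enum):
    """The three ribosomal RNA chains (plus a catch-all)."""

    S16 = "16S"
    S5 = "5S"
    S23 = "23S"
    OTHER = "other"

    @classmethod
    def coerce(cls, value: "Molecule | str") -> "Molecule":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            return cls.OTHER


class Level(str, Enum):
    """Alphabet level at which fragments are compared."""

    RY = "ry"
    AUGC = "augc"

    @classmethod
    def coerce(cls, value: "Level | str") -> "Level":
        return value if isinstance(value, cls) else cls(str(value).lower())


def normalize_residues(raw: str) -> str:
    """Uppercase, T->U, gap characters ('-', '.') -> N.

    Raises ``ValueError`` naming the offending character on anything outside
    A/C/G/T/U/N/-/. (case-insensitive).
    """
    out = []
    for ch in raw.upper():
        if ch in "-.":
            out.append("N")
        elif ch == "T":
            out.append("U")
        elif ch in RNA_ALPHABET:
            out.append(ch)
        else:
            raise ValueError(f"disallowed residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class RnaSequence:
    """One rRNA chain over {A,U,G,C,N}; N is a reconstructed gap."""

    id: str
    residues: str
    molecule: Molecule = Molecule.OTHER

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues outside AUGCN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ConcatenatedAncestor:
    """Ordered 16S + 5S + 23S chains of one ancestor, with boundary offsets.

    ``offsets[i]`` is the 0-based start of segment ``i`` in the concatenation;
    ``total_length`` is the summed nucleotide length (4428 for the ancestral
    chains of lengths 1472 + 120 + 2836).
    """

    segments: tuple[RnaSequence, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("at least one segment required")

    @classmethod
    def from_sequences(cls, seqs: Iterable[RnaSequence]) -> "ConcatenatedAncestor":
        return cls(tuple(seqs))

    @property
    def offsets(self) -> tuple[int, ...]:
        starts = []
        pos = 0
        for seg in self.segments:
            starts.append(pos)
            pos += len(seg)
        return tuple(starts)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.segments)

    @property
    def sequence(self) -> str:
        return "".join(s.residues for s in self.segments)

    def segment_at(self, concat_pos0: int) -> tuple[int, int]:
        """(segment index, molecule-local 0-based offset) for a concat position."""
        if not 0 <= concat_pos0 < self.total_length:
            raise IndexError(concat_pos0)
        for i in reversed(range(len(self.segments))):
            if concat_pos0 >= self.offsets[i]:
                return i, concat_pos0 - self.offsets[i]
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class EncodedSequence:
    """A concatenated ancestor projected to one alphabet level.

    RY level maps A,G -> R and U,C -> Y; AUGC level is the identity.  N is
    preserved at both levels (and excluded from k-mer matching downstream).
    """

    level: Level
    symbols: str
    source: ConcatenatedAncestor = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.symbols) != self.source.total_length:
            raise ValueError("encoded length must equal source total_length")


def encode(concat: ConcatenatedAncestor, level: Level | str) -> EncodedSequence:
    """Project a concatenated ancestor to the RY or AUGC level."""
    level = Level.coerce(level)
    raw = concat.sequence
    symbols = raw.translate(RY_MAP) if level is Level.RY else raw
    return EncodedSequence(level=level, symbols=symbols, source=concat)


def encode_string(residues: str, level: Level | str) -> str:
    """Encode a bare residue string (used for orthologous-arrangement checks)."""
    return residues.translate(RY_MAP) if Level.coerce(level) is Level.RY else residues
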