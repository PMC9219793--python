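"""Mapping fragments into extant-species coordinates and scoring conservation.

Ancestral fragments are projected onto orthologous positions of extant rRNAs
through pairwise global alignments.  A fragment counts as conserved in a
species when every one of its positions maps (no deletion in the target),
the mapped span has the fragment's length, and the target substring encodes
to the identical arrangement at the fragment's alphabet level.  Conservation
tiers: ``AB_conserved`` needs a match in both archaea and bacteria;
``universal`` needs matches in at least 5 of the 6 kingdoms (archaea,
bacteria, protists, fungi, plants, animals).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio import Align

from .repeats import Fragment
from .seq import Level, Molecule, RnaSequence, encode_string

KINGDOMS = ("archaea", "bacteria", "protists", "fungi", "plants", "animals")


class Tier(str, Enum):
    NONE = "none"
    AB_CONSERVED = "AB_conserved"
    UNIVERSAL = "universal"


def pairwise_align(
    a: RnaSequence,
    b: RnaSequence,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> tuple[str, str, float]:
    """Optimal global alignment of two chains under an affine gap scheme.

    The first residue of a gap run costs ``gap_open`` and every further
    residue ``gap_extend``.  Returns the two gapped rows ('-' for gaps) and
    the optimal score; the traceback is deterministic for fixed inputs.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a.residues, b.residues)[0]
    ga, gb = _gapped_rows(a.residues, b.residues, aln)
    return ga, gb, aln.score


def _gapped_rows(a: str, b: str, aln) -> tuple[str, str]:
    ra, rb = [], []
    coords = aln.coordinates
    for ci in range(coords.shape[1] - 1):
        a0, a1 = coords[0, ci], coords[0, ci + 1]
        b0, b1 = coords[1, ci], coords[1, ci + 1]
        if a1 > a0 and b1 > b0:
            ra.append(a[a0:a1])
            rb.append(b[b0:b1])
        elif a1 > a0:
            ra.append(a[a0:a1])
            rb.append("-" * (a1 - a0))
        else:
            ra.append("-" * (b1 - b0))
            rb.append(b[b0:b1])
    return "".join(ra), "".join(rb)


@dataclass(frozen=True)
class CoordinateMap:
    """Monotone 1-based position pairs between two chains (non-gap columns only)."""

    source_id: str
    target_id: str
    pairs: tuple[tuple[int, int], ...]
    molecule: Molecule = Molecule.OTHER

    def __post_init__(self) -> None:
        prev = (0, 0)
        for p in self.pairs:
            if p[0] <= prev[0] or p[1] <= prev[1]:
                raise ValueError("coordinate pairs must be strictly increasing")
            prev = p

    def to_target(self) -> dict[int, int]:
        return dict(self.pairs)

    def transpose(self) -> "CoordinateMap":
        return CoordinateMap(
            source_id=self.target_id,
            target_id=self.source_id,
            pairs=tuple((t, s) for s, t in self.pairs),
            molecule=self.molecule,
        )


def build_coordinate_map(
    aligned_a: str,
    aligned_b: str,
    source_id: str = "a",
    target_id: str = "b",
    molecule: Molecule = Molecule.OTHER,
) -> CoordinateMap:
    """One (source, target) pair per alignment column where neither row gaps."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows must have equal length")
    pairs = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if ca != "-" and cb != "-":
            pairs.append((ia, ib))
    return CoordinateMap(source_id, target_id, tuple(pairs), molecule)


def orthologous_arrangement(
    fragment: Fragment,
    cmap: CoordinateMap,
    target: RnaSequence,
    level: Level | str | None = None,
) -> str | None:
    """Target-species arrangement spanned by the fragment, or None.

    Undefined (None) when any fragment position is unmapped (deleted in the
    target) or the mapped span's length differs from k (an insertion breaks
    the arrangement).
    """
    if cmap.molecule is not Molecule.OTHER and cmap.molecule != fragment.molecule:
        raise ValueError(
            f"coordinate map is for {cmap.molecule.value}, fragment is "
            f"{fragment.molecule.value}"
        )
    level = Level.coerce(level) if level is not None else fragment.level
    to_tgt = cmap.to_target()
    mapped = []
    for pos in range(fragment.start, fragment.end + 1):
        tgt = to_tgt.get(pos)
        if tgt is None:
            return None
        mapped.append(tgt)
    span = mapped[-1] - mapped[0] + 1
    if span != fragment.k:
        return None
    sub = target.residues[mapped[0] - 1 : mapped[-1]]
    if "N" in sub:
        return None
    return encode_string(sub, level)


@dataclass(frozen=True)
class SpeciesAlignment:
    """One extant species' chain with its map from the ancestral molecule."""

    species_id: str
    kingdom: str
    cmap: CoordinateMap
    target: RnaSequence

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-species match flags and the derived conservation tier for one fragment."""

    fragment: Fragment
    species_matches: tuple[tuple[str, bool], ...]
    kingdoms_matched: frozenset[str]
    kingdoms_evaluated: frozenset[str]
    tier: Tier
    partial: bool  # True when some kingdom had no species to evaluate


def classify_conservation(
    fragment: Fragment,
    species: list[SpeciesAlignment],
    level: Level | str | None = None,
) -> ConservationProfile:
    """Tier a fragment by which kingdoms preserve its position and arrangement.

    A kingdom matches when any of its species does.  Kingdoms with no
    supplied species are excluded from evaluation and the profile is flagged
    partial.
    """
    level = Level.coerce(level) if level is not None else fragment.level
    if fragment.level is Level.RY and level is Level.AUGC:
        raise ValueError("an RY-level arrangement cannot be compared at AUGC level")
    # RY coarsening is the identity on an already-RY arrangement
    expected = encode_string(fragment.arrangement, level)
    matches = []
    matched_kingdoms: set[str] = set()
    evaluated = {sp.kingdom for sp in species}
    if not evaluated:
        raise ValueError("at least one species required")
    for sp in species:
        relevant = sp.cmap.molecule in (Molecule.OTHER, fragment.molecule)
        arr = (
            orthologous_arrangement(fragment, sp.cmap, sp.target, level)
            if relevant
            else None
        )
        ok = arr is not None and arr == expected
        matches.append((sp.species_id, bool(ok)))
        if ok:
            matched_kingdoms.add(sp.kingdom)

    if len(matched_kingdoms) >= 5:
        tier = Tier.UNIVERSAL
    elif {"archaea", "bacteria"} <= matched_kingdoms:
        tier = Tier.AB_CONSERVED
    else:
        tier = Tier.NONE
    return ConservationProfile(
        fragment=fragment,
        species_matches=tuple(matches),
        kingdoms_matched=frozenset(matched_kingdoms),
        kingdoms_evaluated=frozenset(evaluated),
        tier=tier,
        partial=len(evaluated) < len(KINGDOMS),
    )
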