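"""Detection and filtering of repeated short fragments ("local self-similarities").

A *fragment* is one occurrence of a k-mer whose symbol arrangement occurs at
least twice along the concatenated 16S+5S+23S ancestor at a given alphabet
level.  k-mers containing N (reconstructed gaps) or spanning a molecule
boundary are never candidates.  Heavily overlapping occurrences are treated
as redundant (pseudo-positive) information and removed by a greedy left-to-
right scan: a candidate is discarded iff it overlaps an already-retained
fragment by strictly more than ``threshold * k`` nucleotides (default 40%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .seq import ConcatenatedAncestor, EncodedSequence, Level, Molecule


@dataclass(frozen=True)
class Fragment:
    """One occurrence of a repeated k-mer, molecule-local 1-based inclusive."""

    level: Level
    k: int
    arrangement: str
    molecule: Molecule
    start: int
    end: int
    concat_start: int  # 1-based position in the concatenation
    type_id: int
    conserved_tier: str = "none"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.k:
            raise ValueError("fragment span must equal k")
        if len(self.arrangement) != self.k:
            raise ValueError("arrangement length must equal k")
        if "N" in self.arrangement:
            raise ValueError("arrangement must be N-free")
        if self.start < 1 or self.concat_start < 1:
            raise ValueError("coordinates are 1-based")

    @property
    def concat_interval0(self) -> tuple[int, int]:
        """0-based half-open interval in concatenation coordinates."""
        return self.concat_start - 1, self.concat_start - 1 + self.k


@dataclass(frozen=True)
class FragmentSet:
    """Fragments at one (level, k) after filtering, with summary statistics."""

    level: Level
    k: int
    fragments: tuple[Fragment, ...]

    def __post_init__(self) -> None:
        for f in self.fragments:
            if f.level != self.level or f.k != self.k:
                raise ValueError("all fragments must share the set's level and k")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_types(self) -> int:
        return len({f.arrangement for f in self.fragments})

    @property
    def per_molecule_counts(self) -> dict[Molecule, int]:
        counts: dict[Molecule, int] = defaultdict(int)
        for f in self.fragments:
            counts[f.molecule] += 1
        return dict(counts)

    @property
    def total_length_product(self) -> int:
        return self.k * self.n_fragments

    @property
    def union_span(self) -> int:
        return union_span(self.fragments)

    def overlapped_or_adjacent_fraction(self, gap: int = 0) -> float:
        """Fraction of fragments overlapping or lying within ``gap`` nt of another.

        Computed on concatenation coordinates; ``gap=0`` means directly
        abutting intervals count as adjacent.
        """
        if not self.fragments:
            return 0.0
        ivs = sorted(f.concat_interval0 for f in self.fragments)
        flagged = [False] * len(ivs)
        for i in range(len(ivs) - 1):
            if ivs[i + 1][0] - ivs[i][1] <= gap:
                flagged[i] = flagged[i + 1] = True
        return sum(flagged) / len(ivs)


def _candidate_kmers(encoded: EncodedSequence, k: int):
    """Yield (concat_pos0, arrangement) for N-free k-mers within one molecule."""
    concat = encoded.source
    sym = encoded.symbols
    for seg_idx, seg in enumerate(concat.segments):
        off = concat.offsets[seg_idx]
        for local0 in range(len(seg) - k + 1):
            pos0 = off + local0
            window = sym[pos0 : pos0 + k]
            if "N" not in window:
                yield pos0, window


def find_repeats(encoded: EncodedSequence, k: int) -> list[Fragment]:
    """All occurrences of every arrangement appearing >= 2 times (unfiltered).

    Occurrences carry molecule-local 1-based coordinates; ``type_id`` groups
    identical arrangements (assigned in order of first occurrence, shared
    across molecules).
    """
    if not 2 <= k <= encoded.source.total_length:
        raise ValueError(f"k={k} out of range [2, {encoded.source.total_length}]")
    by_arr: dict[str, list[int]] = defaultdict(list)
    for pos0, window in _candidate_kmers(encoded, k):
        by_arr[window].append(pos0)

    concat = encoded.source
    fragments: list[Fragment] = []
    type_id = 0
    # dict preserves first-occurrence order -> deterministic type ids
    for arrangement, positions in by_arr.items():
        if len(positions) < 2:
            continue
        for pos0 in positions:
            seg_idx, local0 = concat.segment_at(pos0)
            fragments.append(
                Fragment(
                    level=encoded.level,
                    k=k,
                    arrangement=arrangement,
                    molecule=concat.segments[seg_idx].molecule,
                    start=local0 + 1,
                    end=local0 + k,
                    concat_start=pos0 + 1,
                    type_id=type_id,
                )
            )
        type_id += 1
    fragments.sort(key=lambda f: f.concat_start)
    return fragments


@dataclass(frozen=True)
class SweepRecord:
    """Unfiltered repeat statistics at one length k."""

    k: int
    n_fragments: int
    n_types: int
    total_length_product: int
    has_repeat: bool
    exceeds_concat_length: bool  # the pseudo-positive heuristic


def sweep_lengths(
    encoded: EncodedSequence, k_min: int, k_max: int
) -> list[SweepRecord]:
    """Per-k repeat summary for k in [k_min, k_max] (counts before filtering).

    ``exceeds_concat_length`` flags lengths where k times the fragment count
    exceeds the concatenation length, indicating heavy redundancy.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    records = []
    total = encoded.source.total_length
    for k in range(k_min, k_max + 1):
        frags = find_repeats(encoded, k)
        n = len(frags)
        n_types = len({f.arrangement for f in frags})
        records.append(
            SweepRecord(
                k=k,
                n_fragments=n,
                n_types=n_types,
                total_length_product=k * n,
                has_repeat=n > 0,
                exceeds_concat_length=k * n > total,
            )
        )
    return records


def max_repeat_length(records: Sequence[SweepRecord]) -> int | None:
    """Largest k with at least one repeat, or None."""
    ks = [r.k for r in records if r.has_repeat]
    return max(ks) if ks else None


def filter_overlaps(
    fragments: Iterable[Fragment], threshold: float = 0.4
) -> FragmentSet:
    """Greedy overlap filter: keep the leftmost of any pair overlapping > threshold*k.

    Fragments are scanned in ascending ``concat_start`` order (ties by
    arrangement, for determinism); a candidate is discarded iff its overlap
    with an already-retained fragment is strictly greater than
    ``threshold * k`` nucleotides, so an overlap of exactly 40% of k keeps
    both fragments.  A type whose occurrence count drops below 2 afterwards
    is dropped entirely (it is no longer a repeat).
    """
    frags = sorted(fragments, key=lambda f: (f.concat_start, f.arrangement))
    if not frags:
        raise ValueError("cannot filter an empty fragment list")
    level, k = frags[0].level, frags[0].k
    for f in frags:
        if f.level != level or f.k != k:
            raise ValueError("mixed level or k in filter_overlaps input")

    max_overlap = threshold * k
    retained: list[Fragment] = []
    for cand in frags:
        cs, ce = cand.concat_interval0
        drop = False
        for kept in reversed(retained):
            ks_, ke = kept.concat_interval0
            if ke <= cs:
                break  # sorted: earlier fragments end even sooner
            if min(ce, ke) - max(cs, ks_) > max_overlap:
                drop = True
                break
        if not drop:
            retained.append(cand)

    counts: dict[str, int] = defaultdict(int)
    for f in retained:
        counts[f.arrangement] += 1
    final = tuple(f for f in retained if counts[f.arrangement] >= 2)
    return FragmentSet(level=level, k=k, fragments=final)


def intersect_treatments(
    luca: FragmentSet,
    archaea: FragmentSet,
    bacteria: FragmentSet,
    mode: str = "off",
) -> FragmentSet:
    """Restrict the focal (LUCA) set to arrangements repeated in all three ancestors.

    ``mode="arrangement"`` keeps a LUCA fragment iff its arrangement is a
    repeat type in the archaeal and bacterial sets too; ``mode="off"``
    (default) passes the LUCA set through unchanged.
    """
    for other in (archaea, bacteria):
        if other.level != luca.level or other.k != luca.k:
            raise ValueError("treatment sets must share level and k")
    if mode == "off":
        return luca
    if mode != "arrangement":
        raise ValueError(f"unknown intersection mode {mode!r}")
    shared = (
        {f.arrangement for f in luca.fragments}
        & {f.arrangement for f in archaea.fragments}
        & {f.arrangement for f in bacteria.fragments}
    )
    kept = tuple(f for f in luca.fragments if f.arrangement in shared)
    return FragmentSet(level=luca.level, k=luca.k, fragments=kept)


def union_span(fragments: Iterable[Fragment]) -> int:
    """Distinct nucleotide positions covered, per molecule, summed over molecules."""
    by_mol: dict[Molecule, list[tuple[int, int]]] = defaultdict(list)
    for f in fragments:
        by_mol[f.molecule].append((f.start, f.end))
    total = 0
    for ivs in by_mol.values():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
        total += cur_e - cur_s + 1
    return total
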