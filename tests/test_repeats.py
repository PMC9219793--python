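"""k-mer repeat detection, overlap filtering and interval statistics."""

import numpy as np
import pytest

from selfsim import (
    ConcatenatedAncestor,
    Fragment,
    FragmentSet,
    Level,
    Molecule,
    RnaSequence,
    encode,
    filter_overlaps,
    find_repeats,
    intersect_treatments,
    max_repeat_length,
    sweep_lengths,
    union_span,
)

from conftest import bitmap_union_span, make_concat


def one_molecule(residues, molecule=Molecule.S16):
    return ConcatenatedAncestor(
        (RnaSequence(id=molecule.value, residues=residues, molecule=molecule),)
    )


def brute_force_repeats(symbols, boundaries, k):
    """All repeated N-free k-mer occurrences by direct window comparison.

    ``boundaries`` are 0-based segment start offsets; windows crossing a
    boundary are excluded.
    """
    cuts = set(boundaries[1:])
    windows = {}
    for i in range(len(symbols) - k + 1):
        if any(i < c < i + k for c in cuts):
            continue
        w = symbols[i : i + k]
        if "N" in w:
            continue
        windows.setdefault(w, []).append(i)
    return {
        w: positions for w, positions in windows.items() if len(positions) >= 2
    }


class TestEncode:
    def test_ry_mapping(self):
        enc = encode(one_molecule("GAUC"), "ry")
        assert enc.symbols == "RRYY"

    def test_n_preserved(self):
        assert encode(one_molecule("GANC"), "ry").symbols == "RRNY"

    def test_augc_is_identity(self):
        assert encode(one_molecule("GAUC"), "augc").symbols == "GAUC"


class TestFindRepeats:
    def test_enumeration_of_eight_mer(self):
        """Matches brute-force enumeration of all 4-mers of 'AUGGAUGG'."""
        enc = encode(one_molecule("AUGGAUGG"), "augc")
        frags = find_repeats(enc, 4)
        got = {(f.arrangement, f.start) for f in frags}
        want = {
            (w, p + 1)
            for w, ps in brute_force_repeats("AUGGAUGG", [0], 4).items()
            for p in ps
        }
        assert got == want
        assert {f.arrangement for f in frags} == {"AUGG"}  # 'UGGA' occurs once

    def test_all_distinct_symbols_no_repeats(self):
        enc = encode(one_molecule("AUGC"), "augc")
        assert find_repeats(enc, 2) == []

    def test_molecule_boundary_excluded(self):
        # 'GG|GG' shares a 2-mer across the 16S/5S junction only
        concat = ConcatenatedAncestor(
            (
                RnaSequence(id="16S", residues="AUGG", molecule=Molecule.S16),
                RnaSequence(id="5S", residues="GGUA", molecule=Molecule.S5),
            )
        )
        frags = find_repeats(encode(concat, "augc"), 2)
        # "GG" occurs within 16S (pos 3-4) and within 5S (pos 1-2) but the
        # straddling window (16S pos4 + 5S pos1) must not appear
        gg = [(f.molecule, f.start) for f in frags if f.arrangement == "GG"]
        assert (Molecule.S16, 3) in gg and (Molecule.S5, 1) in gg
        assert all(
            f.start + f.k - 1 <= 4 for f in frags
        )  # no window extends past a segment

    def test_n_containing_kmers_excluded(self):
        enc = encode(one_molecule("AUNGAUNG"), "augc")
        frags = find_repeats(enc, 3)
        assert all("N" not in f.arrangement for f in frags)

    def test_random_agrees_with_brute_force(self, rng):
        concat = make_concat(rng, lengths=(50, 15, 60), n_frac=0.05)
        for level in ("ry", "augc"):
            enc = encode(concat, level)
            for k in (2, 3, 5):
                got = {(f.arrangement, f.concat_start) for f in find_repeats(enc, k)}
                want = {
                    (w, p + 1)
                    for w, ps in brute_force_repeats(
                        enc.symbols, list(concat.offsets), k
                    ).items()
                    for p in ps
                }
                assert got == want

    def test_type_id_shared_across_molecules(self, rng):
        concat = ConcatenatedAncestor(
            (
                RnaSequence(id="16S", residues="GGAAUUCC", molecule=Molecule.S16),
                RnaSequence(id="23S", residues="CCGGAAUU", molecule=Molecule.S23),
            )
        )
        frags = find_repeats(encode(concat, "augc"), 4)
        by_type = {}
        for f in frags:
            by_type.setdefault(f.arrangement, set()).add(f.type_id)
        for ids in by_type.values():
            assert len(ids) == 1

    def test_k_out_of_range(self):
        enc = encode(one_molecule("AUGC"), "augc")
        with pytest.raises(ValueError):
            find_repeats(enc, 1)
        with pytest.raises(ValueError):
            find_repeats(enc, 5)


class TestSweep:
    def test_no_repeats_all_k_flagged_empty(self):
        enc = encode(one_molecule("AUGC"), "augc")
        recs = sweep_lengths(enc, 2, 4)
        assert all(not r.has_repeat for r in recs)
        assert max_repeat_length(recs) is None

    def test_shared_k1_mer_forces_both_sub_k_pairs(self):
        """A repeated (k+1)-mer implies its prefix and suffix k-mers repeat."""
        # plant the same 7-mer at two well-separated sites
        seven = "AUGGCUA"
        backbone = seven + "CCCCCGGGGAA" + seven + "UUUGG"
        enc = encode(one_molecule(backbone), "augc")
        frags7 = find_repeats(enc, 7)
        assert seven in {f.arrangement for f in frags7}
        frags6 = {f.arrangement for f in find_repeats(enc, 6)}
        assert seven[:6] in frags6 and seven[1:] in frags6

    def test_counts_non_increasing_after_projection(self, rng):
        """Projecting each (k+1)-repeat to its k-sub-repeats never exceeds the
        direct k count (verified against a brute-force recount)."""
        concat = make_concat(rng, lengths=(300, 60, 400))
        enc = encode(concat, "ry")
        recs = {r.k: r for r in sweep_lengths(enc, 4, 10)}
        for k in range(4, 10):
            # positions of (k+1) repeats project into positions of k repeats
            pos_k = {f.concat_start for f in find_repeats(enc, k)}
            for f in find_repeats(enc, k + 1):
                assert f.concat_start in pos_k
                assert f.concat_start + 1 in pos_k
            assert recs[k].n_fragments >= recs[k + 1].n_fragments

    def test_pseudo_positive_flag(self, rng):
        concat = make_concat(rng, lengths=(200, 40, 260))
        enc = encode(concat, "ry")
        recs = sweep_lengths(enc, 2, 3)
        # at k=2 on a 500-nt RY sequence virtually every position repeats
        assert recs[0].exceeds_concat_length
        assert recs[0].total_length_product == 2 * recs[0].n_fragments


def frag(start, k=11, concat_start=None, arrangement=None, mol=Molecule.S16,
         level=Level.RY, type_id=0):
    return Fragment(
        level=level,
        k=k,
        arrangement=arrangement or "R" * k,
        molecule=mol,
        start=start,
        end=start + k - 1,
        concat_start=concat_start if concat_start is not None else start,
        type_id=type_id,
    )


class TestFilterOverlaps:
    def test_majority_overlap_drops_second(self):
        # k=11 at 1-11 and 6-16: overlap 6 nt = 54.5% > 40% -> rightmost dropped
        fs = filter_overlaps([frag(1), frag(6)])
        assert [f.start for f in fs.fragments] == []  # type count fell below 2

    def test_majority_overlap_keeps_leftmost_when_type_survives(self):
        fs = filter_overlaps([frag(1), frag(6), frag(40)])
        assert [f.start for f in fs.fragments] == [1, 40]

    def test_minor_overlap_keeps_both(self):
        # overlap 3 nt = 27.3% of 11
        fs = filter_overlaps([frag(1), frag(9)])
        assert [f.start for f in fs.fragments] == [1, 9]

    def test_exactly_forty_percent_keeps_both(self):
        # k=10, overlap exactly 4 nt: the rule is strict 'higher than 40%'
        fs = filter_overlaps([frag(1, k=10), frag(7, k=10)])
        assert [f.start for f in fs.fragments] == [1, 7]

    def test_order_invariance_and_never_grows(self, rng):
        frags = [
            frag(int(s), concat_start=int(s), type_id=0)
            for s in sorted(rng.choice(np.arange(1, 400), size=25, replace=False))
        ]
        shuffled = list(frags)
        rng.shuffle(shuffled)
        a = filter_overlaps(frags)
        b = filter_overlaps(shuffled)
        assert a.fragments == b.fragments
        assert a.n_fragments <= len(frags)

    def test_retained_pairs_respect_threshold(self, rng):
        starts = sorted(rng.choice(np.arange(1, 300), size=30, replace=False))
        fs = filter_overlaps([frag(int(s), concat_start=int(s)) for s in starts])
        ivs = [f.concat_interval0 for f in fs.fragments]
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                ov = min(ivs[i][1], ivs[j][1]) - max(ivs[i][0], ivs[j][0])
                assert ov <= 0.4 * fs.k

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            filter_overlaps([frag(1, k=10), frag(30, k=11)])


class TestIntersectTreatments:
    def make_set(self, arrangements, level=Level.RY, k=4):
        frags = []
        pos = 1
        for tid, arr in enumerate(arrangements):
            for _ in range(2):
                frags.append(
                    frag(pos, k=k, concat_start=pos, arrangement=arr,
                         level=level, type_id=tid)
                )
                pos += k + 2
        return FragmentSet(level=level, k=k, fragments=tuple(frags))

    def test_identity_inputs(self):
        s = self.make_set(["RRYY", "RYRY"])
        assert intersect_treatments(s, s, s, mode="arrangement") == s

    def test_default_mode_is_passthrough(self):
        luca = self.make_set(["RRYY", "RYRY"])
        other = self.make_set(["YYYY"])
        assert intersect_treatments(luca, other, other) == luca

    def test_focal_only_arrangement_dropped(self):
        luca = self.make_set(["RRYY", "RYRY"])
        arch = self.make_set(["RRYY"])
        bact = self.make_set(["RRYY", "YYRR"])
        out = intersect_treatments(luca, arch, bact, mode="arrangement")
        assert {f.arrangement for f in out.fragments} == {"RRYY"}

    def test_level_mismatch_rejected(self):
        with pytest.raises(ValueError):
            intersect_treatments(
                self.make_set(["RRYY"]),
                self.make_set(["AUGC"], level=Level.AUGC),
                self.make_set(["RRYY"]),
                mode="arrangement",
            )


class TestUnionSpan:
    def test_disjoint_is_k_times_n(self):
        fs = [frag(1), frag(50), frag(100)]
        assert union_span(fs) == 33

    def test_overlap_counted_once(self):
        assert union_span([frag(1), frag(9)]) == 19  # 11 + 11 - 3

    def test_random_equals_bitmap_oracle(self, rng):
        for _ in range(100):
            n = rng.integers(1, 12)
            frags = [
                frag(
                    int(rng.integers(1, 200)),
                    mol=Molecule.S16 if rng.random() < 0.5 else Molecule.S23,
                )
                for _ in range(n)
            ]
            assert union_span(frags) == bitmap_union_span(frags)


class TestProjectionProperty:
    def test_augc_repeats_are_ry_repeats(self, rng):
        """RY is a coarsening: every AUGC repeat projects onto an RY repeat."""
        for seed in range(5):
            concat = make_concat(
                np.random.default_rng(seed), lengths=(150, 40, 200)
            )
            for k in (3, 4, 5):
                augc_pos = {
                    f.concat_start
                    for f in find_repeats(encode(concat, "augc"), k)
                }
                ry_pos = {
                    f.concat_start for f in find_repeats(encode(concat, "ry"), k)
                }
                assert augc_pos <= ry_pos
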