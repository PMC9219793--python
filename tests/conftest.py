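"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from selfsim import (
    CharacterMatrix,
    ConcatenatedAncestor,
    MkModel,
    Molecule,
    RnaSequence,
    read_newick,
)

BASES = "AUGC"


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_rna(rng, length, ids="seq", molecule=Molecule.OTHER, n_frac=0.0):
    chars = rng.choice(list(BASES + "N"), size=length, p=[(1 - n_frac) / 4] * 4 + [n_frac])
    return RnaSequence(id=ids, residues="".join(chars), molecule=molecule)


def make_concat(rng, lengths=(60, 20, 80), n_frac=0.0):
    mols = (Molecule.S16, Molecule.S5, Molecule.S23)
    return ConcatenatedAncestor(
        tuple(
            random_rna(rng, ln, ids=m.value, molecule=m, n_frac=n_frac)
            for m, ln in zip(mols, lengths)
        )
    )


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle for marginal ancestral likelihoods
# ---------------------------------------------------------------------------

def enumeration_marginal(tree, matrix: CharacterMatrix, site: int, target=None,
                         model: MkModel | None = None) -> np.ndarray:
    """Marginal state vector at ``target`` by brute-force joint enumeration.

    Sums the joint probability of every assignment of states to every node
    (uniform root prior, transition probabilities along each edge, indicator
    weights at observed tips), then marginalizes onto the target node.
    Exponential in node count; meant for trees with a handful of nodes.
    """
    import itertools

    model = model or MkModel()
    t = tree.tree
    target = t.seed_node if target is None else target
    nodes = list(t.preorder_node_iter())
    idx = {n: i for i, n in enumerate(nodes)}
    edges = [
        (idx[n.parent_node], idx[n], model.transition_matrix(n.edge.length or 0.0))
        for n in nodes
        if n is not t.seed_node
    ]
    tip_obs = {}
    for n in nodes:
        if n.is_leaf():
            tip_obs[idx[n]] = int(matrix.row(n.taxon.label)[site])

    out = np.zeros(5)
    for assignment in itertools.product(range(5), repeat=len(nodes)):
        ok = all(
            obs == 5 or assignment[i] == obs for i, obs in tip_obs.items()
        )
        if not ok:
            continue
        p = 1.0
        for pi, ci, P in edges:
            p *= P[assignment[pi], assignment[ci]]
        out[assignment[idx[target]]] += p
    return out / out.sum()


# ---------------------------------------------------------------------------
# brute-force global affine alignment oracle (enumerates all alignments)
# ---------------------------------------------------------------------------

def brute_force_alignment_score(a, b, match=2.0, mismatch=-1.0,
                                gap_open=-5.0, gap_extend=-1.0):
    """Optimal score by recursive enumeration of every gapped alignment.

    The first residue of a gap run costs gap_open, later ones gap_extend —
    the same convention the aligner uses.  No memoization; exponential.
    """
    best = [-np.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, "M", score + s)
        if i < len(a):
            rec(i + 1, j, "A", score + (gap_extend if prev == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score + (gap_extend if prev == "B" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# bitmap oracles for interval statistics
# ---------------------------------------------------------------------------

def bitmap_union_span(fragments) -> int:
    masks = {}
    for f in fragments:
        masks.setdefault(f.molecule, set()).update(range(f.start, f.end + 1))
    return sum(len(s) for s in masks.values())


def bitmap_functional_count(intervals, catalog) -> int:
    covered = {}
    for mol, start, end in intervals:
        covered.setdefault(Molecule.coerce(mol), set()).update(range(start, end + 1))
    return sum(
        1 for mol, pos in catalog.unique_positions() if pos in covered.get(mol, ())
    )
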