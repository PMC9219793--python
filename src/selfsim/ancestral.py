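"""Marginal maximum-likelihood ancestral reconstruction under a 5-state Mk model.

Each alignment column evolves independently on a fixed rooted tree under a
symmetric continuous-time Markov model over the states A, U, G, C and gap
(the gap is an ordinary fifth state, rendered as N in reconstructed
sequences).  With branch lengths measured in expected substitutions per
site, the transition probabilities have the closed form

    p_stay(t)   = 1/5 + (4/5) * exp(-(5/4) * rate * t)
    p_change(t) = (1 - p_stay(t)) / 4

Per-site marginal state probabilities at any node are computed by a pruning
(inside) pass over the subtree below the node combined with an outside
(down) pass carrying the contribution of the rest of the tree; the
reconstructed sequence takes the argmax state per site, ties broken by the
fixed order A < U < G < C < gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import PhyloTree
from .seq import Molecule, RnaSequence

#: fixed state order; argmax tie-breaks follow this order
STATES = ("A", "U", "G", "C", "gap")
N_STATES = 5
UNKNOWN = 5

_CHAR_TO_CODE = {"A": 0, "U": 1, "G": 2, "C": 3, "T": 1, "-": 4, "N": 4, ".": 4, "?": 5, "X": 5}
_CODE_TO_RESIDUE = "AUGCN"  # gap rendered as N


@dataclass(frozen=True)
class MkModel:
    """Symmetric Mk(5) substitution model; gap is the fifth state."""

    rate: float = 1.0

    def p_stay(self, t: float) -> float:
        return 1.0 / N_STATES + (4.0 / 5.0) * np.exp(-(5.0 / 4.0) * self.rate * t)

    def p_change(self, t: float) -> float:
        return (1.0 - self.p_stay(t)) / 4.0

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"negative branch length {t}")
        stay = self.p_stay(t)
        change = self.p_change(t)
        P = np.full((N_STATES, N_STATES), change)
        np.fill_diagonal(P, stay)
        return P


class CharacterMatrix:
    """Aligned per-taxon states coded 0..4 (A,U,G,C,gap) plus 5 for unknown."""

    def __init__(self, taxa: Sequence[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        if codes.ndim != 2 or codes.shape[0] != len(taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if codes.size and (codes.min() < 0 or codes.max() > UNKNOWN):
            raise ValueError("state codes must lie in 0..5")
        self.taxa = list(taxa)
        self.codes = codes
        self._index = {t: i for i, t in enumerate(self.taxa)}
        if len(self._index) != len(self.taxa):
            raise ValueError("duplicate taxon ids")

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.codes[self._index[taxon]]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} missing from character matrix") from None

    @classmethod
    def from_strings(cls, data: dict[str, str]) -> "CharacterMatrix":
        """Build from aligned residue strings (A/U/G/C/T, '-'/'N'/'.' = gap, '?' = unknown)."""
        taxa = list(data)
        lengths = {len(s) for s in data.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal alignment lengths: {sorted(lengths)}")
        codes = np.empty((len(taxa), lengths.pop() if lengths else 0), dtype=np.int8)
        for i, taxon in enumerate(taxa):
            for j, ch in enumerate(data[taxon].upper()):
                try:
                    codes[i, j] = _CHAR_TO_CODE[ch]
                except KeyError:
                    raise ValueError(f"taxon {taxon!r}: bad character {ch!r}") from None
        return cls(taxa, codes)

    @classmethod
    def from_sequences(cls, seqs: Sequence[RnaSequence]) -> "CharacterMatrix":
        return cls.from_strings({s.id: s.residues for s in seqs})


def _tip_partial(codes: np.ndarray) -> np.ndarray:
    """(n_sites, 5) indicator partials; unknown states give the all-ones row."""
    n_sites = codes.shape[0]
    partial = np.zeros((n_sites, N_STATES))
    known = codes != UNKNOWN
    partial[np.arange(n_sites)[known], codes[known]] = 1.0
    partial[~known] = 1.0
    return partial


class MkAncestralModel:
    """Marginal ancestral-state model on a fixed tree and aligned matrix.

    Parameters
    ----------
    tree
        Rooted tree with branch lengths in expected substitutions per site.
    matrix
        Aligned states for every tip of the tree.
    model
        Substitution model; default unit-rate symmetric Mk(5).
    """

    def __init__(self, tree: PhyloTree, matrix: CharacterMatrix, model: MkModel | None = None):
        self.tree = tree
        self.matrix = matrix
        self.model = model or MkModel()
        for label in tree.tip_labels:
            matrix.row(label)  # raises if a tip is missing

    @classmethod
    def from_files(cls, fasta_path, newick_path, model: MkModel | None = None):
        from .io import read_fasta, read_newick

        seqs = read_fasta(fasta_path)
        return cls(read_newick(newick_path), CharacterMatrix.from_sequences(seqs), model)

    # -- likelihood passes -------------------------------------------------

    def _up_pass(self) -> dict[dendropy.Node, np.ndarray]:
        """Conditional (inside) likelihoods, rescaled per node to max 1 per site."""
        up: dict[dendropy.Node, np.ndarray] = {}
        for node in self.tree.tree.postorder_node_iter():
            if node.is_leaf():
                partial = _tip_partial(self.matrix.row(node.taxon.label))
            else:
                partial = np.ones((self.matrix.n_sites, N_STATES))
                for child in node.child_nodes():
                    P = self.model.transition_matrix(child.edge.length or 0.0)
                    partial = partial * (up[child] @ P)
                scale = partial.max(axis=1, keepdims=True)
                scale[scale == 0] = 1.0
                partial = partial / scale
            up[node] = partial
        return up

    def _down_pass(self, up: dict[dendropy.Node, np.ndarray]) -> dict[dendropy.Node, np.ndarray]:
        """Outside likelihoods: contribution of everything except the node's subtree."""
        down: dict[dendropy.Node, np.ndarray] = {}
        root = self.tree.tree.seed_node
        down[root] = np.ones((self.matrix.n_sites, N_STATES))
        for node in self.tree.tree.preorder_node_iter():
            if node is root:
                continue
            parent = node.parent_node
            outside = down[parent].copy()
            for sib in parent.child_nodes():
                if sib is not node:
                    P_sib = self.model.transition_matrix(sib.edge.length or 0.0)
                    outside *= up[sib] @ P_sib
            P = self.model.transition_matrix(node.edge.length or 0.0)
            partial = outside @ P
            scale = partial.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            down[node] = partial / scale
        return down

    def _resolve_node(self, node) -> dendropy.Node:
        if node is None:
            return self.tree.tree.seed_node
        if isinstance(node, dendropy.Node):
            return node
        if isinstance(node, (list, tuple)):
            return self.tree.mrca(*node)
        raise TypeError("node must be None (root), a Node, or a tuple of tip labels")

    def fit(self, node=None, molecule: Molecule | str = Molecule.OTHER,
            name: str = "ancestor") -> "AncestralReconstruction":
        """Reconstruct the marginal state distribution at ``node``.

        ``node`` may be None (the root), a tree node, or a tuple of tip
        labels whose MRCA is used — so a clade ancestor is addressed without
        relying on internal node labels.
        """
        target = self._resolve_node(node)
        up = self._up_pass()
        if target is self.tree.tree.seed_node:
            joint = up[target].copy()
        else:
            down = self._down_pass(up)
            joint = up[target] * down[target]
        total = joint.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("zero likelihood at some site (conflicting data?)")
        probs = joint / total
        return AncestralReconstruction(
            node_name=name,
            site_probabilities=probs,
            molecule=Molecule.coerce(molecule),
            model=self.model,
        )


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-site marginal state probabilities and the argmax sequence at a node."""

    node_name: str
    site_probabilities: np.ndarray  # (n_sites, 5), rows sum to 1
    molecule: Molecule = Molecule.OTHER
    model: MkModel = field(default_factory=MkModel)

    def __post_init__(self) -> None:
        sums = self.site_probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("site probability vectors must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.site_probabilities.shape[0]

    @property
    def argmax_codes(self) -> np.ndarray:
        # np.argmax takes the first maximum -> ties break A < U < G < C < gap
        return np.argmax(self.site_probabilities, axis=1)

    @property
    def sequence(self) -> RnaSequence:
        residues = "".join(_CODE_TO_RESIDUE[c] for c in self.argmax_codes)
        return RnaSequence(id=self.node_name, residues=residues, molecule=self.molecule)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.site_probabilities, columns=["pA", "pU", "pG", "pC", "pGap"]
        )
        df.insert(0, "site", np.arange(1, self.n_sites + 1))
        df["state"] = [_CODE_TO_RESIDUE[c] for c in self.argmax_codes]
        return df

    def write_site_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        codes = self.argmax_codes
        max_p = self.site_probabilities.max(axis=1)
        counts = {STATES[s]: int((codes == s).sum()) for s in range(N_STATES)}
        lines = [
            f"Ancestral reconstruction: {self.node_name}",
            f"  sites: {self.n_sites}  (rate = {self.model.rate:g})",
            "  state counts: " + ", ".join(f"{k}={v}" for k, v in counts.items()),
            f"  mean max posterior: {max_p.mean():.4f}",
            f"  sites with max posterior < 0.5: {int((max_p < 0.5).sum())}",
        ]
        return "\n".join(lines)


def site_state_likelihoods(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    site: int,
    node=None,
    model: MkModel | None = None,
) -> np.ndarray:
    """Normalized 5-vector of marginal state likelihoods at one site (0-based)."""
    fit = MkAncestralModel(tree, matrix, model).fit(node=node)
    return fit.site_probabilities[site]


def reconstruct_sequence(
    tree: PhyloTree,
    matrix: CharacterMatrix,
    node=None,
    model: MkModel | None = None,
    molecule: Molecule | str = Molecule.OTHER,
    name: str = "ancestor",
) -> AncestralReconstruction:
    """Functional wrapper: reconstruct the argmax ancestral sequence at ``node``."""
    return MkAncestralModel(tree, matrix, model).fit(
        node=node, molecule=molecule, name=name
    )
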