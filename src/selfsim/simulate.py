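"""Ground-truth generators for every pipeline input.

Three generators cover the pipeline end to end: tip alignments evolved from
a known root under the Mk(5) process (the inverse of ancestral
reconstruction), background concatenations with repeats planted at known
coordinates (ground truth for the k-mer search), and extant-species
variants with controlled transition/transversion/indel edits (ground truth
for the conservation mapping; transitions are invisible at the RY level).
All generators are deterministic given their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ancestral import _CHAR_TO_CODE, _CODE_TO_RESIDUE, CharacterMatrix, MkModel, N_STATES
from .io import PhyloTree
from .repeats import find_repeats
from .seq import ConcatenatedAncestor, Level, Molecule, RnaSequence, encode

PURINES = "AG"
PYRIMIDINES = "UC"
_TRANSITION = {"A": "G", "G": "A", "U": "C", "C": "U"}


@dataclass(frozen=True)
class PlantedFragment:
    """One arrangement written into the background at known coordinates."""

    level: Level
    k: int
    arrangement: str
    positions: tuple[tuple[Molecule, int], ...]  # (molecule, 1-based start)


@dataclass(frozen=True)
class Edit:
    kind: str  # transition | transversion | deletion | insertion
    position: int  # 1-based, in the original sequence
    old: str
    new: str


@dataclass(frozen=True)
class SimulationTruth:
    """Everything a test needs to score the pipeline against the generator."""

    seed: int
    root_sequence: RnaSequence | None = None
    branch_changes: Mapping[str, int] = field(default_factory=dict)
    planted: tuple[PlantedFragment, ...] = ()
    edits: tuple[Edit, ...] = ()


def simulate_mk_tips(
    tree: PhyloTree,
    root: RnaSequence,
    model: MkModel | None = None,
    seed: int = 0,
) -> tuple[CharacterMatrix, SimulationTruth]:
    """Evolve the root sequence down the tree site-independently.

    Each branch applies the closed-form Mk(5) transition: a site keeps its
    state with probability p_stay(t) and otherwise moves uniformly to one of
    the other four.  Branch change counts (sites whose state differs across
    the branch) are recorded per child node in the truth table, keyed by tip
    label or a stable internal index.
    """
    model = model or MkModel()
    rng = np.random.default_rng(seed)
    codes = np.fromiter(
        (_CHAR_TO_CODE[ch] for ch in root.residues), dtype=np.int8, count=len(root)
    )
    states: dict = {tree.tree.seed_node: codes}
    branch_changes: dict[str, int] = {}
    tip_rows: dict[str, np.ndarray] = {}
    internal_idx = 0
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_states = states[node.parent_node]
        stay = model.p_stay(t)
        changed = rng.random(parent_states.shape[0]) > stay
        child = parent_states.copy()
        if changed.any():
            # uniform over the 4 non-parent states
            shift = rng.integers(1, N_STATES, size=int(changed.sum()))
            child[changed] = (parent_states[changed] + shift) % N_STATES
        states[node] = child
        if node.is_leaf():
            label = node.taxon.label
            tip_rows[label] = child
        else:
            label = f"internal_{internal_idx}"
            internal_idx += 1
        branch_changes[label] = int((child != parent_states).sum())

    matrix = CharacterMatrix(list(tip_rows), np.vstack(list(tip_rows.values())))
    truth = SimulationTruth(seed=seed, root_sequence=root, branch_changes=branch_changes)
    return matrix, truth


def _realize_arrangement(arrangement: str, level: Level, rng: np.random.Generator) -> str:
    if level is Level.AUGC:
        return arrangement
    out = []
    for ch in arrangement:
        pool = PURINES if ch == "R" else PYRIMIDINES
        out.append(pool[rng.integers(2)])
    return "".join(out)


def plant_repeats(
    segment_lengths: Mapping[Molecule | str, int],
    plants: Sequence[PlantedFragment],
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
    reject_extra_repeats: bool = True,
    max_attempts: int = 1000,
) -> tuple[ConcatenatedAncestor, SimulationTruth]:
    """Random background with known repeats written at known coordinates.

    The background is drawn iid from ``composition`` (default uniform over
    A/U/G/C, no N); each planted occurrence is then written at its declared
    molecule-local position (RY arrangements realized independently per
    occurrence, R as A or G, Y as U or C).  With ``reject_extra_repeats``
    the background is redrawn until, at every planted (level, k), the
    repeat search recovers exactly the planted truth table — the rejection
    criterion is itself the oracle tests rely on.  Caps at ``max_attempts``
    then raises.
    """
    composition = dict(composition or {"A": 0.25, "U": 0.25, "G": 0.25, "C": 0.25})
    letters = list(composition)
    probs = np.array([composition[c] for c in letters], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("composition must sum to 1")
    molecules = [Molecule.coerce(m) for m in segment_lengths]
    lengths = list(segment_lengths.values())

    # validate plant placement before any drawing
    seen: dict[Molecule, set[int]] = {m: set() for m in molecules}
    for plant in plants:
        for mol, start in plant.positions:
            mol = Molecule.coerce(mol)
            if mol not in seen:
                raise ValueError(f"plant in undeclared molecule {mol}")
            length = lengths[molecules.index(mol)]
            if not 1 <= start <= length - plant.k + 1:
                raise ValueError(f"plant at {mol.value}:{start} outside segment")
            span = set(range(start, start + plant.k))
            if seen[mol] & span:
                raise ValueError("overlapping plant positions")
            seen[mol] |= span

    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        segs = []
        for mol, length in zip(molecules, lengths):
            chars = rng.choice(len(letters), size=length)
            residues = list("".join(letters[i] for i in chars))
            segs.append((mol, residues))
        for plant in plants:
            for mol, start in plant.positions:
                mol = Molecule.coerce(mol)
                realized = _realize_arrangement(plant.arrangement, plant.level, rng)
                _, residues = segs[molecules.index(mol)]
                residues[start - 1 : start - 1 + plant.k] = realized
        concat = ConcatenatedAncestor(
            tuple(
                RnaSequence(id=mol.value, residues="".join(res), molecule=mol)
                for mol, res in segs
            )
        )
        if not reject_extra_repeats or _exact_recovery(concat, plants):
            truth = SimulationTruth(seed=seed, planted=tuple(plants))
            return concat, truth
    raise RuntimeError(f"no clean background found in {max_attempts} attempts")


def _exact_recovery(concat: ConcatenatedAncestor, plants: Sequence[PlantedFragment]) -> bool:
    for level, k in {(p.level, p.k) for p in plants}:
        found = {
            (f.molecule, f.start)
            for f in find_repeats(encode(concat, level), k)
        }
        expected = {
            (Molecule.coerce(mol), start)
            for p in plants
            if (p.level, p.k) == (level, k)
            for mol, start in p.positions
        }
        if found != expected:
            return False
    return True


def mutate_variant(
    seq: RnaSequence,
    n_transitions: int = 0,
    n_transversions: int = 0,
    n_indels: int = 0,
    seed: int = 0,
) -> tuple[RnaSequence, tuple[Edit, ...]]:
    """Apply controlled edits at distinct uniformly chosen non-N positions.

    Transitions swap within purines/pyrimidines (A<->G, U<->C) and are
    therefore silent at the RY level; transversions cross the classes;
    indels delete the chosen base or insert a random base before it (50/50).
    Substitutions are applied in original coordinates, then indels from the
    right so that recorded positions stay valid.
    """
    n_edits = n_transitions + n_transversions + n_indels
    eligible = [i for i, ch in enumerate(seq.residues) if ch != "N"]
    if n_edits > len(eligible):
        raise ValueError("more edits requested than editable positions")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(eligible), size=n_edits, replace=False)
    positions = [eligible[i] for i in picks]
    residues = list(seq.residues)
    edits: list[Edit] = []

    idx = 0
    for _ in range(n_transitions):
        pos = positions[idx]
        idx += 1
        old = residues[pos]
        new = _TRANSITION[old]
        residues[pos] = new
        edits.append(Edit("transition", pos + 1, old, new))
    for _ in range(n_transversions):
        pos = positions[idx]
        idx += 1
        old = residues[pos]
        pool = PYRIMIDINES if old in PURINES else PURINES
        new = pool[rng.integers(2)]
        residues[pos] = new
        edits.append(Edit("transversion", pos + 1, old, new))

    indel_positions = sorted(positions[idx:], reverse=True)
    for pos in indel_positions:
        old = residues[pos]
        if rng.random() < 0.5:
            del residues[pos]
            edits.append(Edit("deletion", pos + 1, old, ""))
        else:
            new = "AUGC"[rng.integers(4)]
            residues.insert(pos, new)
            edits.append(Edit("insertion", pos + 1, "", new))

    mutated = RnaSequence(
        id=f"{seq.id}_variant", residues="".join(residues), molecule=seq.molecule
    )
    return mutated, tuple(edits)
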