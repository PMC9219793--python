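"""Readers and writers for every external representation the pipeline touches.

FASTA goes through Bio.SeqIO and Newick through dendropy; the fragment table
and the functional-site catalogue are plain TSV with 1-based inclusive
coordinates (a BED export with 0-based half-open intervals is provided as a
secondary writer).  Run configuration is YAML or JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .repeats import Fragment, FragmentSet
from .seq import Level, Molecule, RnaSequence, normalize_residues

FRAGMENT_COLUMNS = [
    "level",
    "k",
    "type_id",
    "arrangement",
    "molecule",
    "start_1based",
    "end_1based_inclusive",
    "concat_start",
    "conserved_tier",
]

CATALOG_COLUMNS = ["molecule", "position", "category", "source"]


class ParseError(ValueError):
    """Malformed external file; message names the file and offending record."""


def read_fasta(
    path: str | Path, molecule_hint: Molecule | str = Molecule.OTHER
) -> list[RnaSequence]:
    """Read a (multi-)FASTA of rRNA sequences.

    T is normalized to U, '-' and '.' to N, case to upper; record order is
    preserved.  Any character outside A/C/G/T/U/N/-/. raises :class:`ParseError`
    naming the record.
    """
    molecule = Molecule.coerce(molecule_hint)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            residues = normalize_residues(str(rec.seq))
            records.append(RnaSequence(id=rec.id, residues=residues, molecule=molecule))
        except ValueError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def read_aligned_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA rows preserving '-' alignment gaps (as opposed to N states).

    Returns (id, string) pairs with case upper, T->U and '.' -> '-'; used for
    pre-aligned pairwise inputs where '-' marks an alignment gap while N is a
    genuine sequence state.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper().replace("T", "U").replace(".", "-")
        bad = set(s) - (set("AUGCN-"))
        if bad:
            raise ParseError(f"{path}: record {rec.id!r}: bad characters {sorted(bad)}")
        rows.append((rec.id, s))
    return rows


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with branch lengths in expected substitutions per site."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def mrca(self, *tip_labels: str) -> dendropy.Node:
        """Most recent common ancestor of the named tips (the root for none)."""
        if not tip_labels:
            return self.tree.seed_node
        node = self.tree.mrca(taxon_labels=list(tip_labels))
        if node is None:
            raise KeyError(f"tips not found: {tip_labels}")
        return node


def read_newick(path_or_string: str | Path) -> PhyloTree:
    """Parse a single rooted Newick tree; missing branch lengths become 0.

    Duplicate tip labels or malformed parentheses raise :class:`ParseError`.
    """
    text = None
    p = Path(str(path_or_string))
    if p.exists():
        text = p.read_text()
    else:
        text = str(path_or_string)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several unrelated types
        raise ParseError(f"cannot parse Newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ParseError(f"duplicate tip labels: {sorted(dupes)}")
    missing = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing = True
        elif edge.length < 0:
            raise ParseError(f"negative branch length {edge.length}")
    if missing:
        warnings.warn("missing branch lengths set to 0", stacklevel=2)
    return PhyloTree(tree=tree)


@dataclass(frozen=True)
class FunctionalSiteCatalog:
    """Catalogue of (molecule, 1-based E. coli position, category, source) rows.

    The same position may appear under several function categories; for
    counting purposes :meth:`unique_positions` de-duplicates to distinct
    (molecule, position) pairs.
    """

    entries: tuple[tuple[Molecule, int, str, str], ...]

    def unique_positions(self) -> set[tuple[Molecule, int]]:
        return {(mol, pos) for mol, pos, _, _ in self.entries}

    def positions_for(self, molecule: Molecule | str) -> set[int]:
        molecule = Molecule.coerce(molecule)
        return {pos for mol, pos, _, _ in self.entries if mol == molecule}


def read_functional_catalog(path: str | Path) -> FunctionalSiteCatalog:
    """Read a TSV functional-site catalogue (molecule, position, category, source)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty functional catalogue", stacklevel=2)
        return FunctionalSiteCatalog(entries=())
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty functional catalogue", stacklevel=2)
        return FunctionalSiteCatalog(entries=())
    entries = []
    for i, row in df.iterrows():
        mol_raw = str(row["molecule"])
        molecule = Molecule.coerce(mol_raw)
        if molecule is Molecule.OTHER and mol_raw not in ("other",):
            raise ParseError(f"{path}: row {i}: unknown molecule {mol_raw!r}")
        try:
            pos = int(row["position"])
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{path}: row {i}: non-integer position {row['position']!r}"
            ) from exc
        if pos < 1:
            raise ParseError(f"{path}: row {i}: position must be >= 1")
        entries.append((molecule, pos, str(row["category"]), str(row["source"])))
    return FunctionalSiteCatalog(entries=tuple(entries))


def bundled_catalog_path() -> Path:
    """Path of the packaged (partial) E. coli functional-site catalogue."""
    return Path(__file__).parent / "data" / "ecoli_functional_sites.tsv"


def fragment_table(fs: FragmentSet) -> pd.DataFrame:
    rows = [
        {
            "level": f.level.value,
            "k": f.k,
            "type_id": f.type_id,
            "arrangement": f.arrangement,
            "molecule": f.molecule.value,
            "start_1based": f.start,
            "end_1based_inclusive": f.end,
            "concat_start": f.concat_start,
            "conserved_tier": f.conserved_tier,
        }
        for f in sorted(fs.fragments, key=lambda f: f.concat_start)
    ]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_fragment_table(fs: FragmentSet, path: str | Path) -> None:
    """TSV fragment table, sorted by concat_start; read-back reproduces the set."""
    fragment_table(fs).to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> FragmentSet:
    df = pd.read_csv(path, sep="\t", dtype={"arrangement": str})
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ParseError(f"{path}: fragment table has no rows; level/k unknown")
    fragments = tuple(
        Fragment(
            level=Level.coerce(row.level),
            k=int(row.k),
            arrangement=row.arrangement,
            molecule=Molecule.coerce(row.molecule),
            start=int(row.start_1based),
            end=int(row.end_1based_inclusive),
            concat_start=int(row.concat_start),
            type_id=int(row.type_id),
            conserved_tier=str(row.conserved_tier),
        )
        for row in df.itertuples()
    )
    return FragmentSet(level=fragments[0].level, k=fragments[0].k, fragments=fragments)


def write_fragment_bed(fs: FragmentSet, path: str | Path) -> None:
    """Secondary BED export: 0-based half-open, chrom = molecule name."""
    with open(path, "w") as fh:
        for f in sorted(fs.fragments, key=lambda f: (f.molecule.value, f.start)):
            name = f"type{f.type_id}_{f.arrangement}"
            fh.write(f"{f.molecule.value}\t{f.start - 1}\t{f.end}\t{name}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
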