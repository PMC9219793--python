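"""End-to-end orchestration: reconstruct -> encode -> search -> conserve -> enrich.

One run configuration (YAML/JSON) drives the full analysis and produces
per-stage artifacts (FASTA, fragment TSV, sweep TSV, conservation TSV,
enrichment JSON) plus a machine-readable report whose totals mirror the
summary-table row structure: fragment counts, the per-molecule split,
conserved and universal counts, and the functional-site test.  Every stage
is skippable by supplying its input artifact directly, and a rerun with the
same config and seeds writes a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import conservation as cons
from . import io as sio
from .ancestral import CharacterMatrix, MkAncestralModel, MkModel
from .enrichment import EnrichmentTest
from .repeats import (
    FragmentSet,
    filter_overlaps,
    find_repeats,
    max_repeat_length,
    sweep_lengths,
)
from .seq import ConcatenatedAncestor, Level, Molecule, RnaSequence, encode

SCHEMA_VERSION = 1
MOLECULES = (Molecule.S16, Molecule.S5, Molecule.S23)


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated run configuration; see ``RunConfig.from_dict`` for the schema."""

    out_dir: Path
    level: Level = Level.RY
    k: int | None = 11
    sweep: tuple[int, int] | None = None
    overlap_threshold: float = 0.4
    intersection_mode: str = "off"
    # reconstruction inputs (used when ancestor_fasta is absent)
    alignments: dict[Molecule, Path] = field(default_factory=dict)
    tree: Path | None = None
    node: tuple[str, ...] | None = None  # tip labels whose MRCA is the ancestor
    rate: float = 1.0
    # direct stage inputs (each one skips the stage that would produce it)
    ancestor_fasta: dict[Molecule, Path] = field(default_factory=dict)
    fragments: Path | None = None
    # conservation / enrichment
    species_table: Path | None = None
    catalog: Path | None = None
    total_positions: int | None = None
    target_species: str | None = None
    reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_threshold < 1:
            raise ValueError("overlap_threshold must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.sweep is not None:
            lo, hi = self.sweep
            if not 2 <= lo <= hi:
                raise ValueError(f"bad sweep range {self.sweep}")
        if self.k is None and self.sweep is None:
            raise ValueError("need k or sweep")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def molpaths(d):
            return {Molecule.coerce(m): Path(p) for m, p in (d or {}).items()}

        sweep = raw.get("sweep")
        return cls(
            out_dir=Path(raw["out_dir"]),
            level=Level.coerce(raw.get("level", "ry")),
            k=raw.get("k", None if sweep else 11),
            sweep=tuple(sweep) if sweep else None,
            overlap_threshold=float(raw.get("overlap_threshold", 0.4)),
            intersection_mode=str(raw.get("intersection_mode", "off")),
            alignments=molpaths(raw.get("alignments")),
            tree=Path(raw["tree"]) if raw.get("tree") else None,
            node=tuple(raw["node"]) if raw.get("node") else None,
            rate=float(raw.get("rate", 1.0)),
            ancestor_fasta=molpaths(raw.get("ancestor_fasta")),
            fragments=Path(raw["fragments"]) if raw.get("fragments") else None,
            species_table=Path(raw["species_table"]) if raw.get("species_table") else None,
            catalog=Path(raw["catalog"]) if raw.get("catalog") else None,
            total_positions=raw.get("total_positions"),
            target_species=raw.get("target_species"),
            reps=int(raw.get("reps", 10_000)),
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(sio.load_config(path))

    def resolved(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path):
                v = str(v)
            elif isinstance(v, dict):
                v = {getattr(k, "value", str(k)): str(p) for k, p in v.items()}
            elif isinstance(v, Level):
                v = v.value
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out


def _load_species(table_path: Path, ancestor: ConcatenatedAncestor):
    """Read the species table and build per-species coordinate maps.

    TSV columns: species_id, kingdom, molecule, path.  Each FASTA holds the
    ancestral chain and the species chain; pre-aligned rows (equal lengths,
    gaps as N) are used as-is, otherwise the pair is aligned internally.
    """
    import pandas as pd

    df = pd.read_csv(table_path, sep="\t", comment="#", dtype=str)
    by_mol = {seg.molecule: seg for seg in ancestor.segments}
    species = []
    for row in df.itertuples():
        mol = Molecule.coerce(row.molecule)
        rows = sio.read_aligned_fasta(row.path)
        if len(rows) != 2:
            raise ValueError(f"{row.path}: expected 2 records (ancestor, species)")
        (_, ga), (tgt_id, gb) = rows
        if "-" in ga or "-" in gb:
            if len(ga) != len(gb):
                raise ValueError(f"{row.path}: pre-aligned rows differ in length")
        else:
            # raw pair: align the pipeline's ancestor chain to the species chain
            # so fragment coordinates (which include N sites) stay consistent
            tgt_seq = RnaSequence(id=tgt_id, residues=gb, molecule=mol)
            ga, gb, _ = cons.pairwise_align(by_mol[mol], tgt_seq)
        target = RnaSequence(id=tgt_id, residues=gb.replace("-", ""), molecule=mol)
        cmap = cons.build_coordinate_map(
            ga, gb, source_id="ancestor", target_id=row.species_id, molecule=mol
        )
        species.append(
            cons.SpeciesAlignment(
                species_id=row.species_id, kingdom=row.kingdom, cmap=cmap, target=target
            )
        )
    return species


def run(config: RunConfig | dict | str | Path) -> dict:
    """Execute the pipeline and return the report dict (also written to disk)."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_file(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.resolved(),
        "stages": {},
    }

    # -- stage: ancestral reconstruction (skipped when sequences supplied) --
    try:
        ancestor = _stage_ancestor(config, out, report)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reconstruct", exc) from exc

    # -- stage: repeat search + overlap filter ------------------------------
    try:
        frag_set = _stage_search(config, ancestor, out, report)
    except Exception as exc:
        raise StageError("search", exc) from exc

    # -- stage: conservation ------------------------------------------------
    species = None
    if config.species_table is not None:
        try:
            frag_set, species = _stage_conserve(config, ancestor, frag_set, out, report)
        except Exception as exc:
            raise StageError("conserve", exc) from exc

    # -- stage: enrichment ----------------------------------------------------
    if config.catalog is not None:
        try:
            _stage_enrich(config, frag_set, species, out, report)
        except Exception as exc:
            raise StageError("enrich", exc) from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def _stage_ancestor(config: RunConfig, out: Path, report: dict) -> ConcatenatedAncestor:
    segs = []
    if config.ancestor_fasta:
        for mol in MOLECULES:
            if mol not in config.ancestor_fasta:
                continue
            recs = sio.read_fasta(config.ancestor_fasta[mol], molecule_hint=mol)
            segs.append(recs[0])
        report["stages"]["reconstruct"] = {"skipped": True}
    else:
        if config.tree is None or not config.alignments:
            raise ValueError("need ancestor_fasta, or alignments plus tree")
        tree = sio.read_newick(config.tree)
        model = MkModel(rate=config.rate)
        for mol, path in config.alignments.items():
            seqs = sio.read_fasta(path, molecule_hint=mol)
            matrix = CharacterMatrix.from_sequences(seqs)
            fit = MkAncestralModel(tree, matrix, model).fit(
                node=config.node, molecule=mol, name=f"ancestor_{mol.value}"
            )
            sio.write_fasta([fit.sequence], out / f"ancestor_{mol.value}.fasta")
            fit.write_site_table(out / f"ancestor_{mol.value}_sites.tsv")
            segs.append(fit.sequence)
        report["stages"]["reconstruct"] = {
            "skipped": False,
            "molecules": [s.molecule.value for s in segs],
            "lengths": [len(s) for s in segs],
        }
    order = {m: i for i, m in enumerate(MOLECULES)}
    segs.sort(key=lambda s: order.get(s.molecule, 99))
    return ConcatenatedAncestor(tuple(segs))


def _stage_search(
    config: RunConfig, ancestor: ConcatenatedAncestor, out: Path, report: dict
) -> FragmentSet | None:
    info: dict = {"total_length": ancestor.total_length, "level": config.level.value}
    encoded = encode(ancestor, config.level)

    if config.sweep is not None:
        records = sweep_lengths(encoded, *config.sweep)
        sweep_path = out / "sweep.tsv"
        with open(sweep_path, "w") as fh:
            fh.write(
                "k\tn_fragments\tn_types\ttotal_length_product\t"
                "has_repeat\texceeds_concat_length\n"
            )
            for r in records:
                fh.write(
                    f"{r.k}\t{r.n_fragments}\t{r.n_types}\t{r.total_length_product}\t"
                    f"{r.has_repeat}\t{r.exceeds_concat_length}\n"
                )
        info["sweep"] = {
            "k_range": list(config.sweep),
            "max_repeat_length": max_repeat_length(records),
            "empty_k": [r.k for r in records if not r.has_repeat],
        }

    frag_set = None
    if config.fragments is not None:
        frag_set = sio.read_fragment_table(config.fragments)
        info["skipped"] = True
    elif config.k is not None:
        raw = find_repeats(encoded, config.k)
        if raw:
            frag_set = filter_overlaps(raw, threshold=config.overlap_threshold)
        else:
            frag_set = FragmentSet(level=config.level, k=config.k, fragments=())
        info["n_unfiltered"] = len(raw)

    if frag_set is not None:
        sio.write_fragment_table(frag_set, out / "fragments.tsv")
        info.update(
            {
                "k": frag_set.k,
                "n_fragments": frag_set.n_fragments,
                "n_types": frag_set.n_types,
                "per_molecule": {
                    m.value: c for m, c in sorted(frag_set.per_molecule_counts.items())
                },
                "union_span": frag_set.union_span if frag_set.fragments else 0,
                "total_length_product": frag_set.total_length_product,
                "overlapped_or_adjacent_fraction": round(
                    frag_set.overlapped_or_adjacent_fraction(), 4
                ),
            }
        )
    report["stages"]["search"] = info
    return frag_set


def _stage_conserve(config, ancestor, frag_set, out, report):
    species = _load_species(config.species_table, ancestor)
    profiles = [
        cons.classify_conservation(f, species) for f in frag_set.fragments
    ]
    tiers = [p.tier.value for p in profiles]
    with open(out / "conservation.tsv", "w") as fh:
        fh.write(
            "molecule\tstart_1based\tend_1based_inclusive\tarrangement\t"
            "tier\tkingdoms_matched\tspecies_matches\n"
        )
        for frag, prof in zip(frag_set.fragments, profiles):
            kd = ",".join(sorted(prof.kingdoms_matched))
            sp = ",".join(s for s, ok in prof.species_matches if ok)
            fh.write(
                f"{frag.molecule.value}\t{frag.start}\t{frag.end}\t"
                f"{frag.arrangement}\t{prof.tier.value}\t{kd}\t{sp}\n"
            )
    new_frags = tuple(
        dataclasses.replace(f, conserved_tier=t)
        for f, t in zip(frag_set.fragments, tiers)
    )
    frag_set = FragmentSet(level=frag_set.level, k=frag_set.k, fragments=new_frags)
    sio.write_fragment_table(frag_set, out / "fragments.tsv")
    report["stages"]["conserve"] = {
        "n_species": len(species),
        "n_AB_conserved": sum(
            t in ("AB_conserved", "universal") for t in tiers
        ),
        "n_universal": tiers.count("universal"),
        "partial": bool(profiles and profiles[0].partial),
    }
    return frag_set, species


def _map_fragments_to_target(frag_set, species, target_species):
    """Project fragment intervals into one extant species' coordinates."""
    maps = {
        sp.cmap.molecule: sp.cmap
        for sp in species
        if sp.species_id == target_species
    }
    if not maps:
        raise ValueError(f"target species {target_species!r} not in species table")
    intervals = []
    for f in frag_set.fragments:
        cmap = maps.get(f.molecule)
        if cmap is None:
            continue
        to_tgt = cmap.to_target()
        mapped = [to_tgt.get(p) for p in range(f.start, f.end + 1)]
        if any(m is None for m in mapped):
            continue
        intervals.append((f.molecule, min(mapped), max(mapped)))
    return intervals


def _stage_enrich(config, frag_set, species, out, report):
    catalog = sio.read_functional_catalog(config.catalog)
    if config.total_positions is None:
        raise ValueError("enrichment requires total_positions")
    if species and config.target_species:
        intervals = _map_fragments_to_target(frag_set, species, config.target_species)
    else:
        # fragments already carry catalogue coordinates
        intervals = list(frag_set.fragments)
    test = EnrichmentTest(
        intervals, catalog, total_positions=config.total_positions, reps=config.reps
    )
    result = test.run(seed=config.seed)
    result.to_json(out / "enrichment.json")
    result.write_null_tsv(out / "null_distribution.tsv")
    report["stages"]["enrich"] = result.to_dict()
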