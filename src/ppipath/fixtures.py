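"""Seeded synthetic database-dialect files with known ground truth.

Every generator writes the full set of inputs the pipeline consumes — a
PINA-style table, an iRefIndex-style MITAB table, a STRING links file with
its alias file, and the 5-column identifier-mapping TSV — plus independent
bookkeeping (per-database interaction sets, truth table, truth graph,
overlap summary) so parsing, mapping, combining and searching can all be
checked against known answers without any download.

Generation is fully determined by the seed: the same seed reproduces
byte-identical files.  A configurable fraction of decoy records with
unmappable protein names (default 5%) is interleaved to exercise the
discard rule; decoy STRING rows use internal IDs absent from the alias
file.  Fake PubMed IDs are drawn from [10000000, 39999999] and carry no
semantic meaning; the STRING species prefix is fixed at "9606." to mimic
the real links-file shape.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import integration
from .formats import DEFAULT_STRING_THRESHOLD, StandardTable
from .graph import IREFINDEX, PINA, STRING, PPIGraph
from .idmapping import MappingEntry, write_mapping_entries
from .integration import CanonicalRecordSet, OverlapSummary

ALL_SOURCES = (PINA, IREFINDEX, STRING)

_PINA_HEADER = "ID(s) interactor A\tID(s) interactor B\tPublication Identifier(s)"
_IREF_HEADER = "uidA\tuidB\taltA\taltB\taliasA\taliasB\tmethod\tpmids"
_STRING_HEADER = "protein1 protein2 combined_score"
_ALIAS_HEADER = "#string_protein_id\talias\tsource"


@dataclass
class FixtureBundle:
    """Generated files plus the ground truth they encode."""

    pina_path: Path
    iref_path: Path
    string_links_path: Path
    string_alias_path: Path
    mapping_path: Path
    truth_graph: PPIGraph
    truth_table: StandardTable
    truth_overlaps: OverlapSummary
    seed: int
    #: per-db canonical interaction bookkeeping (independent of the parsers)
    per_db: dict[str, CanonicalRecordSet] = field(default_factory=dict)
    #: data lines written per source file (decoys included)
    lines_written: dict[str, int] = field(default_factory=dict)
    #: decoy (unmappable) lines written per source file
    decoys_written: dict[str, int] = field(default_factory=dict)

    @property
    def paths(self) -> list[Path]:
        return [
            self.pina_path,
            self.iref_path,
            self.string_links_path,
            self.string_alias_path,
            self.mapping_path,
        ]


@dataclass(frozen=True)
class _Protein:
    accession: str
    gene_name: str
    synonym: str
    secondary: str
    string_id: str
    reviewed: bool


def _make_proteins(names: Sequence[str], rng: random.Random) -> list[_Protein]:
    proteins = []
    for i, acc in enumerate(names):
        proteins.append(
            _Protein(
                accession=acc,
                gene_name=f"GENE{i}",
                synonym=f"SYN{i}",
                secondary=f"X{90000 + i}",
                string_id=f"9606.ENSP{400000 + i:08d}",
                reviewed=rng.random() < 0.8,
            )
        )
    return proteins


def _write_mapping(proteins: Sequence[_Protein], path: Path) -> None:
    entries = [
        MappingEntry(
            accession=p.accession,
            reviewed=p.reviewed,
            gene_name=p.gene_name,
            synonyms=(p.synonym,),
            secondary_accessions=(p.secondary,),
        )
        for p in proteins
    ]
    write_mapping_entries(entries, path)


def _pina_line(name_a: str, name_b: str, pmids: Sequence[int]) -> str:
    pm = "|".join(f"pubmed:{p}" for p in pmids)
    return f"uniprotkb:{name_a}\tuniprotkb:{name_b}\t{pm}"


def _iref_line(
    p_a: str, p_b: str, alias_a: str, alias_b: str, pmids: Sequence[int]
) -> str:
    pm = "|".join(f"pubmed:{p}" for p in pmids)
    return (
        f"uniprotkb:{p_a}\tuniprotkb:{p_b}\t-\t-\t{alias_a}\t{alias_b}"
        f"\tpsi-mi:MI:0018\t{pm}"
    )


def _fake_pmids(rng: random.Random) -> tuple[int, ...]:
    return tuple(
        sorted({rng.randint(10000000, 39999999) for _ in range(rng.randint(1, 3))})
    )


def _finalize(
    proteins: Sequence[_Protein],
    per_db_raw: dict[str, dict[tuple[str, str], tuple[frozenset[int], Optional[int]]]],
    file_lines: dict[str, list[str]],
    out_dir: Path,
    seed: int,
    lines_written: dict[str, int],
    decoys_written: dict[str, int],
) -> FixtureBundle:
    out_dir.mkdir(parents=True, exist_ok=True)
    pina_path = out_dir / "pina.tsv"
    iref_path = out_dir / "irefindex.tsv"
    links_path = out_dir / "string_links.txt"
    alias_path = out_dir / "string_aliases.tsv"
    mapping_path = out_dir / "mapping.tsv"

    pina_path.write_text(
        "\n".join([_PINA_HEADER] + file_lines[PINA]) + "\n", newline="\n"
    )
    iref_path.write_text(
        "\n".join([_IREF_HEADER] + file_lines[IREFINDEX]) + "\n", newline="\n"
    )
    links_path.write_text(
        "\n".join([_STRING_HEADER] + file_lines[STRING]) + "\n", newline="\n"
    )
    alias_lines = [_ALIAS_HEADER]
    for p in proteins:
        alias_lines.append(f"{p.string_id}\t{p.accession}\tUniProt_AC")
        alias_lines.append(f"{p.string_id}\t{p.gene_name}\tEnsembl_gene")
    alias_path.write_text("\n".join(alias_lines) + "\n", newline="\n")
    _write_mapping(proteins, mapping_path)

    sets = [
        CanonicalRecordSet(source_db=db, interactions=dict(raw))
        for db, raw in per_db_raw.items()
        if raw
    ]
    truth_table, truth_overlaps = integration.combine(sets)
    truth_graph = PPIGraph.from_table(truth_table)
    return FixtureBundle(
        pina_path=pina_path,
        iref_path=iref_path,
        string_links_path=links_path,
        string_alias_path=alias_path,
        mapping_path=mapping_path,
        truth_graph=truth_graph,
        truth_table=truth_table,
        truth_overlaps=truth_overlaps,
        seed=seed,
        per_db={s.source_db: s for s in sets},
        lines_written=lines_written,
        decoys_written=decoys_written,
    )


def gen_random_ppi(
    n_proteins: int,
    n_edges: int,
    source_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    out_dir: str | Path = "fixtures",
    decoy_fraction: float = 0.05,
    extra_source_prob: float = 0.25,
    string_threshold: int = DEFAULT_STRING_THRESHOLD,
) -> FixtureBundle:
    """Random PPI fixture: ``n_edges`` distinct pairs over ``n_proteins``.

    Each edge is assigned a primary source drawn from ``source_mix`` and,
    with probability ``extra_source_prob`` each, additional sources —
    producing the cross-database overlaps the combiner must account for.
    STRING scores are uniform in [string_threshold, 999] so all generated
    STRING rows survive default-threshold parsing; curated lines carry 1-3
    fake PubMed IDs.
    """
    if n_proteins < 2:
        raise ValueError("n_proteins must be >= 2")
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges {n_edges} exceeds maximum {max_edges}")
    mix = source_mix or {PINA: 1 / 3, IREFINDEX: 1 / 3, STRING: 1 / 3}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("source_mix probabilities must sum to 1")
    unknown = set(mix) - set(ALL_SOURCES)
    if unknown:
        raise ValueError(f"unknown sources in mix: {unknown}")

    rng = random.Random(seed)
    proteins = _make_proteins([f"P{10000 + i}" for i in range(n_proteins)], rng)
    by_acc = {p.accession: p for p in proteins}

    all_pairs = [
        (proteins[i].accession, proteins[j].accession)
        for i in range(n_proteins)
        for j in range(i + 1, n_proteins)
    ]
    pairs = sorted(rng.sample(all_pairs, n_edges))

    dbs = sorted(mix)
    weights = [mix[db] for db in dbs]
    per_db_raw: dict[str, dict] = {db: {} for db in ALL_SOURCES}
    file_lines: dict[str, list[str]] = {db: [] for db in ALL_SOURCES}
    lines_written = {db: 0 for db in ALL_SOURCES}
    decoys_written = {db: 0 for db in ALL_SOURCES}
    decoy_counter = 0

    def curated_name(p: _Protein) -> str:
        # exercise the mapping stage: files refer to proteins by accession,
        # gene name, synonym or secondary accession interchangeably
        return rng.choice([p.accession, p.gene_name, p.synonym, p.secondary])

    def emit(db: str, pair: tuple[str, str]) -> None:
        nonlocal decoy_counter
        pa, pb = by_acc[pair[0]], by_acc[pair[1]]
        if db == STRING:
            score = rng.randint(string_threshold, 999)
            per_db_raw[STRING][pair] = (frozenset(), score)
            file_lines[STRING].append(f"{pa.string_id} {pb.string_id} {score}")
            file_lines[STRING].append(f"{pb.string_id} {pa.string_id} {score}")
            lines_written[STRING] += 2
        else:
            pmids = _fake_pmids(rng)
            if pair in per_db_raw[db]:
                old_pmids, _ = per_db_raw[db][pair]
                pmids = tuple(sorted(set(pmids) | old_pmids))
            per_db_raw[db][pair] = (frozenset(pmids), None)
            if db == PINA:
                file_lines[PINA].append(
                    _pina_line(curated_name(pa), curated_name(pb), pmids)
                )
            else:
                file_lines[IREFINDEX].append(
                    _iref_line(
                        curated_name(pa),
                        curated_name(pb),
                        pa.gene_name,
                        pb.gene_name,
                        pmids,
                    )
                )
            lines_written[db] += 1
        if rng.random() < decoy_fraction:
            decoy_counter += 1
            fake = f"ZZDECOY{decoy_counter}"
            if db == STRING:
                score = rng.randint(string_threshold, 999)
                file_lines[STRING].append(f"9606.ENSPFAKE{decoy_counter:06d} {pa.string_id} {score}")
                lines_written[STRING] += 1
            elif db == PINA:
                file_lines[PINA].append(_pina_line(fake, pa.gene_name, _fake_pmids(rng)))
                lines_written[PINA] += 1
            else:
                file_lines[IREFINDEX].append(
                    _iref_line(fake, pa.accession, fake, pa.gene_name, _fake_pmids(rng))
                )
                lines_written[IREFINDEX] += 1
            decoys_written[db] += 1

    for pair in pairs:
        primary = rng.choices(dbs, weights=weights)[0]
        edge_dbs = {primary}
        for db in ALL_SOURCES:
            if db not in edge_dbs and rng.random() < extra_source_prob:
                edge_dbs.add(db)
        for db in sorted(edge_dbs):
            emit(db, pair)

    return _finalize(
        proteins,
        per_db_raw,
        file_lines,
        Path(out_dir),
        seed,
        lines_written,
        decoys_written,
    )


def gen_path_graph(
    layers: Sequence[int], seed: int = 0, out_dir: str | Path = "fixtures"
) -> FixtureBundle:
    """Layered graph from one source to one sink, all edges curated cost 1.

    Consecutive layers are completely connected, so the number of distinct
    shortest source-to-sink paths equals the product of the interior layer
    widths and the shortest cost equals the number of layer gaps.
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    if any(w < 1 for w in layers):
        raise ValueError("layer widths must be >= 1")

    rng = random.Random(seed)
    names: list[list[str]] = []
    flat: list[str] = []
    for li, width in enumerate(layers):
        layer = [f"L{li:02d}N{j:02d}" for j in range(width)]
        names.append(layer)
        flat.extend(layer)
    proteins = _make_proteins(flat, rng)

    per_db_raw: dict[str, dict] = {db: {} for db in ALL_SOURCES}
    file_lines: dict[str, list[str]] = {db: [] for db in ALL_SOURCES}
    lines = 0
    for la, lb in zip(names, names[1:]):
        for a in la:
            for b in lb:
                pair = (a, b) if a <= b else (b, a)
                pmids = _fake_pmids(rng)
                per_db_raw[PINA][pair] = (frozenset(pmids), None)
                file_lines[PINA].append(_pina_line(a, b, pmids))
                lines += 1
    return _finalize(
        proteins,
        per_db_raw,
        file_lines,
        Path(out_dir),
        seed,
        {PINA: lines, IREFINDEX: 0, STRING: 0},
        {db: 0 for db in ALL_SOURCES},
    )


def gen_hub(
    n_neighbors: int, seed: int = 0, out_dir: str | Path = "fixtures"
) -> FixtureBundle:
    """Star graph: one center with ``n_neighbors`` leaves, curated edges."""
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    rng = random.Random(seed)
    center = "HUB00"
    leaves = [f"LF{i:05d}" for i in range(n_neighbors)]
    proteins = _make_proteins([center] + leaves, rng)

    per_db_raw: dict[str, dict] = {db: {} for db in ALL_SOURCES}
    file_lines: dict[str, list[str]] = {db: [] for db in ALL_SOURCES}
    for leaf in leaves:
        pair = (center, leaf) if center <= leaf else (leaf, center)
        pmids = _fake_pmids(rng)
        per_db_raw[PINA][pair] = (frozenset(pmids), None)
        file_lines[PINA].append(_pina_line(center, leaf, pmids))
    return _finalize(
        proteins,
        per_db_raw,
        file_lines,
        Path(out_dir),
        seed,
        {PINA: n_neighbors, IREFINDEX: 0, STRING: 0},
        {db: 0 for db in ALL_SOURCES},
    )
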