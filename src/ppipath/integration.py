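"""Canonicalize raw interaction records and combine sources into one
deduplicated, evidence-merged interaction table with overlap accounting.

Canonicalization resolves every interactor to a primary UniProtKB
accession; records with any unresolvable interactor are discarded and
counted.  Combining unions evidence across databases per unordered pair
and tallies, per database, the valid proteins and interactions, every
pairwise overlap, and the items distinct to a single database — the same
bookkeeping a cross-database comparison table reports.

"Valid protein" means a protein appearing in at least one kept interaction
of that database.  Self-interactions (homodimers) are retained and counted
as interactions.  Private user data participates as one more record set
under a user-chosen source label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formats import RawRecord, StandardRow, StandardTable
from .graph import STRING, PPIError, canonical_pair
from .idmapping import MappingTable


class UsageError(PPIError):
    pass


@dataclass
class CanonicalRecordSet:
    """One source database's interactions after ID mapping and dedup."""

    source_db: str
    #: canonical pair -> (pubmed_ids, string_score)
    interactions: dict[tuple[str, str], tuple[frozenset[int], Optional[int]]] = field(
        default_factory=dict
    )
    discarded_count: int = 0

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.interactions)

    @property
    def proteins(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.interactions:
            out.add(a)
            out.add(b)
        return out


def canonicalize(
    records: Iterable[RawRecord], table: MappingTable
) -> CanonicalRecordSet:
    """Resolve, discard unmappables, and merge duplicate pairs.

    All records must come from a single source database.  Duplicates merge
    by PubMed-ID union and string-score maximum.
    """
    records = list(records)
    if not records:
        raise UsageError("canonicalize requires at least one record")
    source_dbs = {r.source_db for r in records}
    if len(source_dbs) > 1:
        raise UsageError(f"mixed source databases in one record set: {source_dbs}")
    source_db = source_dbs.pop()

    out = CanonicalRecordSet(source_db=source_db)
    for rec in records:
        acc_a = table.resolve(rec.id_a)
        acc_b = table.resolve(rec.id_b)
        if acc_a is None or acc_b is None:
            out.discarded_count += 1
            continue
        pair = canonical_pair(acc_a, acc_b)
        pmids = frozenset(rec.pubmed_ids)
        score = rec.string_score
        if pair in out.interactions:
            old_pmids, old_score = out.interactions[pair]
            pmids |= old_pmids
            if old_score is not None:
                score = old_score if score is None else max(score, old_score)
        out.interactions[pair] = (pmids, score)
    return out


@dataclass
class OverlapSummary:
    """Per-database counts, pairwise overlaps and distinct items.

    The pairwise maps are symmetric and their diagonal equals the per-db
    count; "distinct" means present in exactly one database.
    """

    per_db_proteins: dict[str, int]
    per_db_interactions: dict[str, int]
    pairwise_protein_overlap: dict[tuple[str, str], int]
    pairwise_interaction_overlap: dict[tuple[str, str], int]
    distinct_proteins: dict[str, int]
    distinct_interactions: dict[str, int]

    @property
    def databases(self) -> list[str]:
        return sorted(self.per_db_proteins)

    def protein_overlap(self, a: str, b: str) -> int:
        return self.pairwise_protein_overlap[canonical_pair(a, b)]

    def interaction_overlap(self, a: str, b: str) -> int:
        return self.pairwise_interaction_overlap[canonical_pair(a, b)]


def _overlap_counts(items_by_db: dict[str, set]) -> tuple[dict, dict]:
    pairwise: dict[tuple[str, str], int] = {}
    for db, items in items_by_db.items():
        pairwise[(db, db)] = len(items)
    for a, b in combinations(sorted(items_by_db), 2):
        pairwise[canonical_pair(a, b)] = len(items_by_db[a] & items_by_db[b])
    distinct: dict[str, int] = {}
    for db, items in items_by_db.items():
        others: set = set()
        for other_db, other_items in items_by_db.items():
            if other_db != db:
                others |= other_items
        distinct[db] = len(items - others)
    return pairwise, distinct


def combine(sets: Sequence[CanonicalRecordSet]) -> tuple[StandardTable, OverlapSummary]:
    """Merge canonical record sets into one table plus overlap accounting."""
    if not sets:
        raise UsageError("combine requires at least one record set")
    dbs = [s.source_db for s in sets]
    if len(set(dbs)) != len(dbs):
        raise UsageError(f"duplicate source databases: {dbs}")

    merged: dict[tuple[str, str], dict] = {}
    for s in sorted(sets, key=lambda s: s.source_db):
        for pair, (pmids, score) in s.interactions.items():
            slot = merged.setdefault(
                pair, {"sources": set(), "pmids": set(), "score": None}
            )
            slot["sources"].add(s.source_db)
            slot["pmids"] |= pmids
            if s.source_db == STRING and score is not None:
                slot["score"] = (
                    score if slot["score"] is None else max(score, slot["score"])
                )

    rows = [
        StandardRow(
            acc_a=pair[0],
            acc_b=pair[1],
            sources=frozenset(slot["sources"]),
            pubmed_ids=frozenset(slot["pmids"]),
            string_score=slot["score"],
        )
        for pair, slot in merged.items()
    ]
    table = StandardTable(rows=rows)

    proteins_by_db = {s.source_db: s.proteins for s in sets}
    pairs_by_db = {s.source_db: s.pairs for s in sets}
    prot_pairwise, prot_distinct = _overlap_counts(proteins_by_db)
    int_pairwise, int_distinct = _overlap_counts(pairs_by_db)
    summary = OverlapSummary(
        per_db_proteins={db: len(v) for db, v in proteins_by_db.items()},
        per_db_interactions={db: len(v) for db, v in pairs_by_db.items()},
        pairwise_protein_overlap=prot_pairwise,
        pairwise_interaction_overlap=int_pairwise,
        distinct_proteins=prot_distinct,
        distinct_interactions=int_distinct,
    )
    return table, summary


def overlap_frame(summary: OverlapSummary, kind: str = "interactions") -> pd.DataFrame:
    """Overlap matrix as a DataFrame: one row per database, one column per
    database (diagonal = per-db count) plus a final Distinct column."""
    if kind == "interactions":
        pairwise = summary.pairwise_interaction_overlap
        distinct = summary.distinct_interactions
    elif kind == "proteins":
        pairwise = summary.pairwise_protein_overlap
        distinct = summary.distinct_proteins
    else:
        raise ValueError(f"kind must be 'proteins' or 'interactions', got {kind!r}")
    dbs = summary.databases
    data = {
        db_col: [pairwise[canonical_pair(db_row, db_col)] for db_row in dbs]
        for db_col in dbs
    }
    data["Distinct"] = [distinct[db] for db in dbs]
    return pd.DataFrame(data, index=pd.Index(dbs, name="Database"))


def write_overlap_report(summary: OverlapSummary, path) -> None:
    """Write the protein and interaction overlap matrices to one TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# Overlapping and distinct proteins\n")
        overlap_frame(summary, "proteins").to_csv(fh, sep="\t", lineterminator="\n")
        fh.write("# Overlapping and distinct interactions\n")
        overlap_frame(summary, "interactions").to_csv(fh, sep="\t", lineterminator="\n")
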