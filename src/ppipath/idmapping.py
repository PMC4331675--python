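"""Protein-identifier mapping: any name, synonym or secondary accession to
a primary UniProtKB accession.

The mapping input is a 5-column TSV::

    accession  reviewed  gene_name  synonyms(;-joined)  secondary_accessions(;-joined)

where ``reviewed`` is ``reviewed`` (Swiss-Prot) or ``unreviewed`` (TrEMBL).
Lookups are case-insensitive (gene symbols are case-ambiguous across
sources); display names preserve the original case.  When two entries claim
the same name, the reviewed entry wins; remaining ties break to the
lexicographically smaller accession.  An entry's own primary accession
always resolves to itself, regardless of other entries' synonym claims.

A miss is a value (``None``), never an exception, so callers can implement
the discard rule for unmappable proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .graph import PPIError


class MappingFormatError(PPIError):
    pass


def _norm(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class MappingEntry:
    accession: str
    reviewed: bool
    gene_name: str
    synonyms: tuple[str, ...] = ()
    secondary_accessions: tuple[str, ...] = ()


@dataclass
class MappingTable:
    name_to_accession: dict[str, str] = field(default_factory=dict)
    accession_to_display: dict[str, str] = field(default_factory=dict)
    reviewed: dict[str, bool] = field(default_factory=dict)
    #: secondary-accession tokens that were silently remapped to a primary
    remapped: dict[str, str] = field(default_factory=dict)

    def resolve(self, query: str) -> Optional[str]:
        """Primary accession for ``query``, or ``None`` on a miss."""
        return self.name_to_accession.get(_norm(query))

    def display_name(self, accession: str) -> str:
        return self.accession_to_display.get(accession, accession)

    def known_names(self) -> Iterable[str]:
        return self.name_to_accession.keys()


def resolve(query: str, table: MappingTable) -> Optional[str]:
    """Functional form of :meth:`MappingTable.resolve`."""
    return table.resolve(query)


def build_mapping_from_entries(entries: Iterable[MappingEntry]) -> MappingTable:
    entries = list(entries)
    seen: set[str] = set()
    for e in entries:
        if e.accession in seen:
            raise MappingFormatError(f"duplicate primary accession {e.accession}")
        seen.add(e.accession)

    # Collect every claim on every normalized name, then resolve conflicts
    # deterministically: own-accession claims first, then reviewed entries,
    # then the lexicographically smaller accession.  Resolving from the full
    # claim set makes the table invariant to input row order.
    claims: dict[str, list[tuple[int, int, str]]] = {}

    def claim(name: str, accession: str, reviewed: bool, own: bool) -> None:
        key = _norm(name)
        if not key:
            return
        claims.setdefault(key, []).append(
            (0 if own else 1, 0 if reviewed else 1, accession)
        )

    remapped: dict[str, str] = {}
    for e in entries:
        claim(e.accession, e.accession, e.reviewed, own=True)
        claim(e.gene_name, e.accession, e.reviewed, own=False)
        for syn in e.synonyms:
            claim(syn, e.accession, e.reviewed, own=False)
        for sec in e.secondary_accessions:
            claim(sec, e.accession, e.reviewed, own=False)
            remapped[sec] = e.accession

    table = MappingTable()
    for name, claimants in claims.items():
        table.name_to_accession[name] = min(claimants)[2]
    for e in entries:
        table.accession_to_display[e.accession] = e.gene_name or e.accession
        table.reviewed[e.accession] = e.reviewed
    table.remapped = {
        sec: acc for sec, acc in remapped.items() if table.resolve(sec) == acc
    }
    return table


def read_mapping_entries(path: str | Path) -> list[MappingEntry]:
    path = Path(path)
    entries: list[MappingEntry] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "accession":
                continue  # header
            if len(fields) < 3:
                raise MappingFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-delimited columns"
                )
            acc, reviewed_flag, gene_name = fields[0], fields[1], fields[2]
            synonyms = tuple(s for s in fields[3].split(";") if s) if len(fields) > 3 else ()
            secondary = tuple(s for s in fields[4].split(";") if s) if len(fields) > 4 else ()
            entries.append(
                MappingEntry(
                    accession=acc.strip(),
                    reviewed=reviewed_flag.strip().lower() == "reviewed",
                    gene_name=gene_name.strip(),
                    synonyms=synonyms,
                    secondary_accessions=secondary,
                )
            )
    return entries


def build_mapping(path: str | Path) -> MappingTable:
    """Build a :class:`MappingTable` from the 5-column mapping TSV."""
    return build_mapping_from_entries(read_mapping_entries(path))


def write_mapping_entries(entries: Iterable[MappingEntry], path: str | Path) -> Path:
    path = Path(path)
    lines = ["accession\treviewed\tgene_name\tsynonyms\tsecondary_accessions"]
    for e in entries:
        lines.append(
            "\t".join(
                [
                    e.accession,
                    "reviewed" if e.reviewed else "unreviewed",
                    e.gene_name,
                    ";".join(e.synonyms),
                    ";".join(e.secondary_accessions),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def convert_idmapping(path: str | Path) -> list[MappingEntry]:
    """Convenience reader for a two-column ``name <tab> accession`` file.

    Produces one entry per accession with every associated name as a
    synonym; reviewed status is unknown and recorded as unreviewed.
    """
    by_acc: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip():
                continue
            by_acc.setdefault(fields[1].strip(), []).append(fields[0].strip())
    return [
        MappingEntry(
            accession=acc,
            reviewed=False,
            gene_name=names[0],
            synonyms=tuple(names[1:]),
        )
        for acc, names in sorted(by_acc.items())
    ]
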