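"""Readers for the three PPI download dialects and the standardized TSV.

Three upstream shapes are supported:

* PINA-style tab-delimited interaction tables (MITAB-like): interactor
  columns first, PubMed evidence in a ``pubmed:``-prefixed field;
* iRefIndex-style MITAB tables: same idea, PubMed IDs further right;
* STRING links files (``protein1 protein2 combined_score``) with an alias
  file translating internal ``9606.ENSP...`` IDs to external names.

Parsers locate columns by header name where possible ("interactor a"/"b",
anything containing "pubmed"/"pmid") and fall back to fixed positions,
because bulk downloads vary.  Malformed lines are skipped and counted,
never fatal.

The standardized interaction format is a UTF-8, Unix-newline TSV with
columns ``accA  accB  sources  pmids  string_score  cost`` — the common
shape everything downstream consumes, including the user-editable cost
column (empty = compute the default cost).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .graph import IREFINDEX, PINA, STRING, PPIError, canonical_pair

#: Default minimum STRING combined score retained when parsing links files.
DEFAULT_STRING_THRESHOLD = 700

#: Identifier prefixes stripped from MITAB-style interactor fields.
KNOWN_ID_PREFIXES = ("uniprotkb:", "refseq:", "entrezgene/locuslink:")

_PUBMED_RE = re.compile(r"pubmed:(\d+)", re.IGNORECASE)


class FormatError(PPIError):
    """A file does not conform to the expected dialect."""


@dataclass(frozen=True)
class RawRecord:
    """One interaction line as read from a source file, before ID mapping."""

    id_a: str
    id_b: str
    source_db: str
    pubmed_ids: tuple[int, ...] = ()
    string_score: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id_a.strip() or not self.id_b.strip():
            raise ValueError("interactor identifiers must be non-empty")
        if self.source_db == STRING:
            if self.string_score is None or not 0 < self.string_score < 1000:
                raise ValueError("STRING record requires score in (0, 1000)")
            if self.pubmed_ids:
                raise ValueError("STRING records carry no PubMed IDs")
        elif self.string_score is not None:
            raise ValueError("string_score only valid for STRING records")


@dataclass
class ParseResult:
    """Records parsed from one file plus bookkeeping counts."""

    records: list[RawRecord]
    skipped: int = 0
    #: STRING rows whose internal ID had no alias (STRING dialect only).
    dropped_unaliased: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class StandardRow:
    acc_a: str
    acc_b: str
    sources: frozenset[str]
    pubmed_ids: frozenset[int] = frozenset()
    string_score: Optional[int] = None
    cost_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.acc_a > self.acc_b:
            raise ValueError(f"pair ({self.acc_a}, {self.acc_b}) not canonical")
        if not self.sources:
            raise ValueError("row requires at least one source")
        if self.cost_override is not None and self.cost_override < 1:
            raise ValueError("cost override must be >= 1")
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "pubmed_ids", frozenset(self.pubmed_ids))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.acc_a, self.acc_b)


@dataclass
class StandardTable:
    """Deduplicated interaction rows in canonical pair order."""

    rows: list[StandardRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            if row.pair in seen:
                raise FormatError(f"duplicate pair {row.pair} in table")
            seen.add(row.pair)
        self.rows = sorted(self.rows, key=lambda r: r.pair)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StandardTable):
            return NotImplemented
        return self.rows == other.rows

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.rows}


# ---------------------------------------------------------------------------
# MITAB-style dialects (PINA, iRefIndex)
# ---------------------------------------------------------------------------


def strip_id_prefix(token: str) -> str:
    """Strip a known database prefix; unknown prefixes are kept verbatim."""
    token = token.strip()
    lowered = token.lower()
    for prefix in KNOWN_ID_PREFIXES:
        if lowered.startswith(prefix):
            return token[len(prefix):]
    return token


def _parse_pubmed_field(text: str) -> tuple[int, ...]:
    return tuple(sorted({int(m) for m in _PUBMED_RE.findall(text)}))


def _locate_columns(
    header: Sequence[str], default_pubmed_col: int
) -> tuple[int, int, int]:
    """Find (interactor A, interactor B, pubmed) column indices."""
    col_a, col_b, col_pm = 0, 1, default_pubmed_col
    for i, name in enumerate(header):
        low = name.lower().lstrip("#").strip()
        if "interactor a" in low or low == "uida":
            col_a = i
        elif "interactor b" in low or low == "uidb":
            col_b = i
        elif "pubmed" in low or "pmid" in low or "publication" in low:
            col_pm = i
    return col_a, col_b, col_pm


def _parse_mitab_like(
    path: str | Path, source_db: str, default_pubmed_col: int
) -> ParseResult:
    path = Path(path)
    records: list[RawRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file")
        cols = _locate_columns(header_line.rstrip("\n").split("\t"), default_pubmed_col)
        col_a, col_b, col_pm = cols
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) <= max(col_a, col_b):
                skipped += 1
                continue
            id_a = strip_id_prefix(fields[col_a])
            id_b = strip_id_prefix(fields[col_b])
            if not id_a or not id_b or id_a == "-" or id_b == "-":
                skipped += 1
                continue
            pmids = (
                _parse_pubmed_field(fields[col_pm]) if col_pm < len(fields) else ()
            )
            records.append(
                RawRecord(id_a=id_a, id_b=id_b, source_db=source_db, pubmed_ids=pmids)
            )
    if not records:
        raise FormatError(f"{path}: no parseable interaction lines")
    return ParseResult(records=records, skipped=skipped)


def parse_pina(path: str | Path, pubmed_col: int = 2) -> ParseResult:
    """Parse a PINA-style download (interactors in the first two columns)."""
    return _parse_mitab_like(path, PINA, pubmed_col)


def parse_irefindex(path: str | Path, pubmed_col: int = 7) -> ParseResult:
    """Parse an iRefIndex-style MITAB download."""
    return _parse_mitab_like(path, IREFINDEX, pubmed_col)


# ---------------------------------------------------------------------------
# STRING dialect
# ---------------------------------------------------------------------------


def read_string_aliases(alias_path: str | Path) -> dict[str, str]:
    """Map STRING internal protein IDs to external names (first alias wins)."""
    aliases: dict[str, str] = {}
    with open(alias_path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                continue
            aliases.setdefault(fields[0], fields[1])
    return aliases


def parse_string(
    links_path: str | Path,
    alias_path: str | Path,
    score_threshold: int = DEFAULT_STRING_THRESHOLD,
) -> ParseResult:
    """Parse a STRING links file, keeping rows with score >= threshold.

    Internal IDs are translated through the alias file; rows whose IDs have
    no alias are dropped and counted in ``dropped_unaliased``.
    """
    aliases = read_string_aliases(alias_path)
    records: list[RawRecord] = []
    skipped = 0
    dropped = 0
    with open(links_path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise FormatError(f"{links_path}: empty file")
        for line in fh:
            fields = line.split()
            if len(fields) < 3:
                if line.strip():
                    skipped += 1
                continue
            try:
                score = int(fields[2])
            except ValueError:
                skipped += 1
                continue
            if score < score_threshold:
                continue
            name_a = aliases.get(fields[0])
            name_b = aliases.get(fields[1])
            if name_a is None or name_b is None:
                dropped += 1
                continue
            records.append(
                RawRecord(
                    id_a=name_a, id_b=name_b, source_db=STRING, string_score=score
                )
            )
    return ParseResult(records=records, skipped=skipped, dropped_unaliased=dropped)


# ---------------------------------------------------------------------------
# Standardized interaction TSV
# ---------------------------------------------------------------------------

_STANDARD_HEADER = "accA\taccB\tsources\tpmids\tstring_score\tcost"


def _format_cost(cost: Optional[float]) -> str:
    if cost is None:
        return ""
    return repr(cost) if not float(cost).is_integer() else str(int(cost))


def write_standard(table: StandardTable, path: str | Path) -> Path:
    """Write the standard TSV (UTF-8, Unix newlines, canonical row order)."""
    path = Path(path)
    lines = [_STANDARD_HEADER]
    for row in table.rows:
        lines.append(
            "\t".join(
                [
                    row.acc_a,
                    row.acc_b,
                    ";".join(sorted(row.sources)),
                    ";".join(str(p) for p in sorted(row.pubmed_ids)),
                    "" if row.string_score is None else str(row.string_score),
                    _format_cost(row.cost_override),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_standard(path: str | Path) -> StandardTable:
    """Read a standard TSV; duplicate pairs are a format error naming the pair."""
    path = Path(path)
    rows: list[StandardRow] = []
    with open(path, encoding="utf-8", newline="") as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t")[:2] != ["accA", "accB"]:
            raise FormatError(f"{path}: not a standard interaction TSV")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}:{lineno}: expected 6 columns")
            acc_a, acc_b, sources, pmids, score, cost = fields
            rows.append(
                StandardRow(
                    acc_a=acc_a,
                    acc_b=acc_b,
                    sources=frozenset(sources.split(";")) if sources else frozenset(),
                    pubmed_ids=frozenset(int(p) for p in pmids.split(";") if p),
                    string_score=int(score) if score else None,
                    cost_override=float(cost) if cost else None,
                )
            )
    try:
        return StandardTable(rows=rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None
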