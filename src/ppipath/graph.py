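"""Evidence-annotated undirected PPI graph and its edge-cost model.

Nodes are UniProtKB accessions; each edge carries one evidence entry per
supporting source database.  The cost of an edge is the path-search penalty:
curated sources (PINA, iRefIndex) contribute a default cost of 1, while a
STRING association with combined score *s* contributes

    max(1, log_100(1000 - s))

so that higher-confidence STRING edges are cheaper, bottoming out at 1
(score >= 900).  An edge supported by several sources takes the minimum of
its per-source costs, and a user-supplied override (>= 1) wins outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from difflib import get_close_matches
from typing import Iterable, Iterator, Mapping, Optional

PINA = "PINA"
IREFINDEX = "iRefIndex"
STRING = "STRING"

#: Databases whose records carry PubMed-curated evidence.
CURATED_SOURCES = frozenset({PINA, IREFINDEX})

#: Absolute tolerance for comparing summed floating-point edge costs.
COST_TOLERANCE = 1e-9


class PPIError(Exception):
    """Base class for errors raised by this package."""


class ProteinNotFound(PPIError, KeyError):
    """A queried protein is absent from the graph or mapping table.

    Carries close-name ``suggestions`` so callers can hint at typos.
    """

    def __init__(self, query: str, suggestions: Iterable[str] = ()):
        self.query = query
        self.suggestions = tuple(suggestions)
        msg = f"protein not found: {query!r}"
        if self.suggestions:
            msg += f" (did you mean: {', '.join(self.suggestions)}?)"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered protein pair lexicographically."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionEvidence:
    """One source database's support for an interaction."""

    source_db: str
    pubmed_ids: frozenset[int] = frozenset()
    string_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.source_db == STRING:
            if self.string_score is None:
                raise ValueError("STRING evidence requires a string_score")
            if not 0 < self.string_score < 1000:
                raise ValueError(
                    f"STRING score must lie in (0, 1000), got {self.string_score}"
                )
            if self.pubmed_ids:
                raise ValueError("STRING evidence carries no PubMed IDs")
        elif self.string_score is not None:
            raise ValueError(
                f"string_score only valid for STRING evidence, not {self.source_db}"
            )
        object.__setattr__(self, "pubmed_ids", frozenset(self.pubmed_ids))

    def sort_key(self) -> tuple:
        return (self.source_db, sorted(self.pubmed_ids), self.string_score or 0)


def evidence_cost(ev: InteractionEvidence) -> float:
    """Cost contributed by a single evidence entry."""
    if ev.source_db == STRING:
        assert ev.string_score is not None
        return max(1.0, math.log(1000 - ev.string_score, 100))
    return 1.0


def edge_cost(
    evidence: Iterable[InteractionEvidence], override: Optional[float] = None
) -> float:
    """Cost of an edge: the override if given, else min per-source cost.

    Always >= 1.  Raises ``ValueError`` on an empty evidence list or an
    override below 1.
    """
    if override is not None:
        if override < 1:
            raise ValueError(f"cost override must be >= 1, got {override}")
        return float(override)
    evidence = list(evidence)
    if not evidence:
        raise ValueError("edge requires at least one evidence entry")
    return min(evidence_cost(ev) for ev in evidence)


@dataclass(frozen=True)
class Interaction:
    """An unordered protein pair with merged evidence and a search cost."""

    pair: tuple[str, str]
    evidence: tuple[InteractionEvidence, ...]
    cost: float
    cost_is_override: bool = False

    def __post_init__(self) -> None:
        if self.pair != canonical_pair(*self.pair):
            raise ValueError(f"pair {self.pair} not in canonical order")
        if not self.evidence:
            raise ValueError("interaction requires evidence")
        if self.cost < 1:
            raise ValueError(f"cost must be >= 1, got {self.cost}")
        object.__setattr__(
            self, "evidence", tuple(sorted(self.evidence, key=lambda e: e.sort_key()))
        )

    @property
    def is_self_loop(self) -> bool:
        return self.pair[0] == self.pair[1]


class PPIGraph:
    """Undirected, evidence-annotated interaction graph.

    No parallel edges; self-loops are stored (homodimers) but ignored by
    path search.  Adjacency is kept symmetric by construction.
    """

    def __init__(self) -> None:
        self._edges: dict[tuple[str, str], Interaction] = {}
        self._adjacency: dict[str, set[str]] = {}

    # -- construction -----------------------------------------------------
    def add_interaction(self, interaction: Interaction) -> None:
        a, b = interaction.pair
        if interaction.pair in self._edges:
            raise ValueError(f"duplicate edge {interaction.pair}")
        self._edges[interaction.pair] = interaction
        self._adjacency.setdefault(a, set())
        self._adjacency.setdefault(b, set())
        if a != b:
            self._adjacency[a].add(b)
            self._adjacency[b].add(a)

    @classmethod
    def from_table(cls, table) -> "PPIGraph":
        """Build a graph from a standardized interaction table.

        One edge per row; the cost honours any user override in the table.
        """
        g = cls()
        for row in table.rows:
            evidence = row_evidence(row)
            cost = edge_cost(evidence, row.cost_override)
            g.add_interaction(
                Interaction(
                    pair=canonical_pair(row.acc_a, row.acc_b),
                    evidence=tuple(evidence),
                    cost=cost,
                    cost_is_override=row.cost_override is not None,
                )
            )
        return g

    # -- queries ----------------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._adjacency)

    @property
    def edges(self) -> Mapping[tuple[str, str], Interaction]:
        return self._edges

    def __contains__(self, accession: str) -> bool:
        return accession in self._adjacency

    def __len__(self) -> int:
        return len(self._adjacency)

    def n_edges(self) -> int:
        return len(self._edges)

    def adjacency(self, accession: str) -> frozenset[str]:
        self._require(accession)
        return frozenset(self._adjacency[accession])

    def edge(self, a: str, b: str) -> Interaction:
        return self._edges[canonical_pair(a, b)]

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self._edges

    def neighbors(self, accession: str) -> list[tuple[str, Interaction]]:
        """Neighbors of ``accession`` with the supporting evidence attached.

        Unknown accessions raise :class:`ProteinNotFound` with nearest-name
        suggestions.
        """
        self._require(accession)
        return [
            (nb, self._edges[canonical_pair(accession, nb)])
            for nb in sorted(self._adjacency[accession])
        ]

    def degree(self, accession: str) -> int:
        self._require(accession)
        return len(self._adjacency[accession])

    def _require(self, accession: str) -> None:
        if accession not in self._adjacency:
            suggestions = get_close_matches(accession, self._adjacency.keys(), n=3)
            raise ProteinNotFound(accession, suggestions)

    def iter_edges(self) -> Iterator[Interaction]:
        for pair in sorted(self._edges):
            yield self._edges[pair]

    # -- equality (used by fixture-closure checks) ------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPIGraph):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        if set(self._edges) != set(other._edges):
            return False
        for pair, inter in self._edges.items():
            o = other._edges[pair]
            if inter.evidence != o.evidence:
                return False
            if abs(inter.cost - o.cost) > COST_TOLERANCE:
                return False
            if inter.cost_is_override != o.cost_is_override:
                return False
        return True

    def __repr__(self) -> str:
        return f"PPIGraph({len(self)} nodes, {self.n_edges()} edges)"


def row_evidence(row) -> list[InteractionEvidence]:
    """Reconstruct per-source evidence entries from a standard-table row.

    Curated sources each carry the row's merged PubMed-ID set; the STRING
    entry carries the combined score.
    """
    evidence: list[InteractionEvidence] = []
    for src in sorted(row.sources):
        if src == STRING:
            evidence.append(
                InteractionEvidence(source_db=STRING, string_score=row.string_score)
            )
        else:
            evidence.append(
                InteractionEvidence(
                    source_db=src, pubmed_ids=frozenset(row.pubmed_ids)
                )
            )
    return evidence
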