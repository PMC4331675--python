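"""All-shortest-path enumeration over the evidence-annotated PPI graph.

A single-source Dijkstra run records, for every reachable node, *every*
optimal predecessor whose relaxation ties the best distance within an
absolute tolerance (summed float costs make exact ties unreliable).  The
resulting predecessor DAG is traversed backwards to enumerate every
distinct shortest path.

Two modes:

* cost mode (default): edge weights are the evidence-derived costs, so the
  returned paths minimize total cost;
* step mode (``by_step=True``): every edge counts 1, so the returned paths
  minimize the number of interaction steps regardless of costs.

Self-loops are ignored during search — with all costs >= 1 they can never
lie on a shortest path.  Enumeration is capped (default 100 paths) with an
explicit truncation flag; paths are sorted fewer-steps-first, then
lexicographically, so truncation is reproducible.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

from .graph import (
    COST_TOLERANCE,
    InteractionEvidence,
    PPIGraph,
    ProteinNotFound,
    canonical_pair,
)
from .idmapping import MappingTable

DEFAULT_PATH_CAP = 100


@dataclass
class PredecessorDAG:
    """Single-source shortest-path distances plus all optimal predecessors."""

    source: str
    dist: dict[str, float] = field(default_factory=dict)
    preds: dict[str, set[str]] = field(default_factory=dict)
    by_step: bool = False


@dataclass
class PathSet:
    """All shortest paths between one pair, with per-edge evidence."""

    source: str
    target: str
    total_cost: float
    by_step: bool
    paths: list[tuple[str, ...]]
    per_edge_evidence: dict[tuple[str, str], tuple[InteractionEvidence, ...]] = field(
        default_factory=dict
    )
    truncated: bool = False
    unreachable: bool = False

    @property
    def n_steps(self) -> Optional[int]:
        """Steps in the shortest (fewest-hop) listed path, None if empty."""
        return len(self.paths[0]) - 1 if self.paths else None

    def __len__(self) -> int:
        return len(self.paths)


def dijkstra_predecessors(
    graph: PPIGraph,
    source: str,
    by_step: bool = False,
    tolerance: float = COST_TOLERANCE,
) -> PredecessorDAG:
    """Dijkstra from ``source`` recording every tie-optimal predecessor.

    ``dist`` holds the exact shortest-path cost to every reachable node
    (unreachable nodes are absent); with ``by_step`` every edge is treated
    as cost 1, so ``dist`` is the hop count.
    """
    if source not in graph:
        raise ProteinNotFound(source)
    dag = PredecessorDAG(source=source, by_step=by_step)
    dist = dag.dist
    preds = dag.preds
    dist[source] = 0.0
    settled: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in settled:
            continue
        settled.add(u)
        d = dist[u]  # authoritative; heap entry may be stale
        for v in graph.adjacency(u):
            if v == u:
                continue  # self-loops never shorten a path
            cost = 1.0 if by_step else graph.edge(u, v).cost
            nd = d + cost
            if v not in dist or nd < dist[v] - tolerance:
                dist[v] = nd
                preds[v] = {u}
                heapq.heappush(heap, (nd, v))
            elif abs(nd - dist[v]) <= tolerance:
                preds.setdefault(v, set()).add(u)
    return dag


def enumerate_paths(
    dag: PredecessorDAG, target: str, cap: int = DEFAULT_PATH_CAP
) -> PathSet:
    """Every distinct shortest path to ``target`` via backward DAG traversal.

    If more than ``cap`` paths exist, exactly ``cap`` are returned in sort
    order (fewer steps first, then lexicographic) with ``truncated=True``.
    An unreachable target yields an empty set flagged ``unreachable``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if target not in dag.dist:
        return PathSet(
            source=dag.source,
            target=target,
            total_cost=float("inf"),
            by_step=dag.by_step,
            paths=[],
            unreachable=True,
        )
    if target == dag.source:
        return PathSet(
            source=dag.source,
            target=target,
            total_cost=0.0,
            by_step=dag.by_step,
            paths=[(dag.source,)],
        )

    # The preds relation is acyclic under strictly increasing dist, so a
    # plain recursive walk terminates; memoization is unnecessary at the
    # sizes the cap makes practical.
    paths: list[tuple[str, ...]] = []

    def walk(node: str, suffix: tuple[str, ...]) -> None:
        if node == dag.source:
            paths.append((node,) + suffix)
            return
        for p in sorted(dag.preds.get(node, ())):
            walk(p, (node,) + suffix)

    walk(target, ())
    paths.sort(key=lambda p: (len(p), p))
    truncated = len(paths) > cap
    return PathSet(
        source=dag.source,
        target=target,
        total_cost=dag.dist[target],
        by_step=dag.by_step,
        paths=paths[:cap],
        truncated=truncated,
    )


def _attach_evidence(graph: PPIGraph, path_set: PathSet) -> PathSet:
    for path in path_set.paths:
        for a, b in zip(path, path[1:]):
            pair = canonical_pair(a, b)
            if pair not in path_set.per_edge_evidence:
                path_set.per_edge_evidence[pair] = graph.edge(a, b).evidence
    return path_set


def _resolve_input(
    graph: PPIGraph, query: str, mapping: Optional[MappingTable], role: str
) -> str:
    """Map a gene name or accession to a graph node, naming the failing input."""
    acc = query
    if mapping is not None:
        resolved = mapping.resolve(query)
        if resolved is not None:
            acc = resolved
    if acc not in graph:
        try:
            graph._require(acc)
        except ProteinNotFound as exc:
            raise ProteinNotFound(f"{role} {query!r}", exc.suggestions) from None
    return acc


def shortest_paths(
    graph: PPIGraph,
    source: str,
    target: str,
    mapping: Optional[MappingTable] = None,
    by_step: bool = False,
    cap: int = DEFAULT_PATH_CAP,
    tolerance: float = COST_TOLERANCE,
) -> PathSet:
    """All shortest paths between two proteins, with evidence attached.

    ``source`` and ``target`` may be gene names when a mapping table is
    supplied; otherwise they must be graph accessions.
    """
    src = _resolve_input(graph, source, mapping, "source")
    tgt = _resolve_input(graph, target, mapping, "target")
    dag = dijkstra_predecessors(graph, src, by_step=by_step, tolerance=tolerance)
    return _attach_evidence(graph, enumerate_paths(dag, tgt, cap=cap))


def single_source(
    graph: PPIGraph,
    source: str,
    mapping: Optional[MappingTable] = None,
    by_step: bool = False,
    cap: int = DEFAULT_PATH_CAP,
    tolerance: float = COST_TOLERANCE,
) -> dict[str, PathSet]:
    """Shortest paths from one fixed protein to every reachable protein.

    One Dijkstra run, one :class:`PathSet` per reachable node (the source
    itself excluded), keyed by target accession and ready for per-target
    export so results can be browsed without re-running the search.
    """
    src = _resolve_input(graph, source, mapping, "source")
    dag = dijkstra_predecessors(graph, src, by_step=by_step, tolerance=tolerance)
    out: dict[str, PathSet] = {}
    for target in sorted(dag.dist):
        if target == src:
            continue
        out[target] = _attach_evidence(graph, enumerate_paths(dag, target, cap=cap))
    return out
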