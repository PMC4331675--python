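"""Query-centric subnetwork views.

Three view builders share one output shape:

* :func:`neighborhood_view` — one protein and everything it interacts
  with.  When the protein has more than ``sample_size`` interactions the
  display layer shows a seeded uniform random sample (default 100), while
  the full edge set is retained for the evidence table.
* :func:`multi_view` — a list of query proteins, each designated a *main*
  node (all its mutual edges shown) or an input *leaf* node (only its
  edges to main nodes shown).  Non-query *mediator* proteins that interact
  with at least two main proteins are pulled in with exactly their edges
  to main nodes — scaffold proteins often mediate what looks like a direct
  interaction.
* :func:`path_view` — the proteins on a set of shortest paths act as main
  nodes; mediators adjacent to >= 2 path proteins are added, and per-path
  highlighting metadata is kept so each listed path can be rendered.

Mediator-mediator edges are never drawn.  Style classes (color/size), not
pixel values, are attached per node; concrete styling lives in the export
templates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .graph import InteractionEvidence, PPIGraph, ProteinNotFound, canonical_pair
from .idmapping import MappingTable
from .integration import UsageError
from .pathfind import PathSet, _resolve_input

DEFAULT_SAMPLE_SIZE = 100

#: (color class, size class) per node role
STYLE_MAIN = ("blue", "large")
STYLE_LEAF = ("green", "small")
STYLE_MEDIATOR = ("green", "small")


@dataclass(frozen=True)
class QueryProtein:
    accession: str
    is_main: bool = True


@dataclass
class SubnetworkView:
    main_nodes: frozenset[str]
    input_leaf_nodes: frozenset[str] = frozenset()
    mediator_nodes: frozenset[str] = frozenset()
    #: full edge set with evidence, for the evidence table
    edges: dict[tuple[str, str], tuple[InteractionEvidence, ...]] = field(
        default_factory=dict
    )
    #: ordered display subset (possibly sampled)
    display_edges: list[tuple[str, str]] = field(default_factory=list)
    sampled: bool = False
    style: dict[str, tuple[str, str]] = field(default_factory=dict)
    #: per-path node sequences for table-selected path highlighting
    path_highlights: Optional[list[tuple[str, ...]]] = None
    unreachable: bool = False

    @property
    def nodes(self) -> frozenset[str]:
        return self.main_nodes | self.input_leaf_nodes | self.mediator_nodes


def _styled(view: SubnetworkView) -> SubnetworkView:
    for n in view.main_nodes:
        view.style[n] = STYLE_MAIN
    for n in view.input_leaf_nodes:
        view.style[n] = STYLE_LEAF
    for n in view.mediator_nodes:
        view.style[n] = STYLE_MEDIATOR
    return view


def neighborhood_view(
    graph: PPIGraph,
    protein: str,
    mapping: Optional[MappingTable] = None,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
) -> SubnetworkView:
    """All interaction partners of one protein, display-sampled past
    ``sample_size`` edges (the evidence table always keeps everything)."""
    center = _resolve_input(graph, protein, mapping, "protein")
    edges: dict[tuple[str, str], tuple[InteractionEvidence, ...]] = {}
    leaves: set[str] = set()
    for nb, inter in graph.neighbors(center):
        edges[inter.pair] = inter.evidence
        if nb != center:
            leaves.add(nb)
    ordered = sorted(edges)
    if len(ordered) > sample_size:
        rng = random.Random(seed)
        display = sorted(rng.sample(ordered, sample_size))
        sampled = True
    else:
        display, sampled = ordered, False
    view = SubnetworkView(
        main_nodes=frozenset({center}),
        input_leaf_nodes=frozenset(leaves),
        edges=edges,
        display_edges=display,
        sampled=sampled,
    )
    return _styled(view)


def _mediators(
    graph: PPIGraph, anchor_nodes: frozenset[str], excluded: frozenset[str]
) -> dict[str, set[str]]:
    """Non-excluded nodes adjacent to >= 2 anchors, with their anchor sets."""
    out: dict[str, set[str]] = {}
    candidates: set[str] = set()
    for a in anchor_nodes:
        if a in graph:
            candidates |= graph.adjacency(a)
    for node in candidates - excluded:
        anchors = graph.adjacency(node) & anchor_nodes
        if len(anchors) >= 2:
            out[node] = anchors
    return out


def multi_view(
    graph: PPIGraph,
    queries: Sequence[QueryProtein],
    mapping: Optional[MappingTable] = None,
) -> SubnetworkView:
    """View of several query proteins with main/leaf designation and
    mediator inclusion.  At least one query must be a main node."""
    if not queries:
        raise UsageError("multi_view requires at least one query protein")
    resolved: list[QueryProtein] = []
    for q in queries:
        acc = _resolve_input(graph, q.accession, mapping, "protein")
        resolved.append(QueryProtein(accession=acc, is_main=q.is_main))
    mains = frozenset(q.accession for q in resolved if q.is_main)
    leaves = frozenset(q.accession for q in resolved if not q.is_main) - mains
    if not mains:
        raise UsageError("at least one query must be designated a main node")

    edges: dict[tuple[str, str], tuple[InteractionEvidence, ...]] = {}
    for a in mains:
        for b in mains | leaves:
            if a != b and graph.has_edge(a, b):
                inter = graph.edge(a, b)
                edges[inter.pair] = inter.evidence

    mediators = _mediators(graph, mains, excluded=mains | leaves)
    for med, anchors in mediators.items():
        for a in anchors:
            inter = graph.edge(med, a)
            edges[inter.pair] = inter.evidence

    view = SubnetworkView(
        main_nodes=mains,
        input_leaf_nodes=leaves,
        mediator_nodes=frozenset(mediators),
        edges=edges,
        display_edges=sorted(edges),
    )
    return _styled(view)


def path_view(graph: PPIGraph, path_set: PathSet) -> SubnetworkView:
    """Subnetwork around a set of shortest paths.

    Every node on any enumerated path acts as a main node; off-path
    proteins adjacent to at least two path proteins join as mediators with
    their edges to path nodes (they mark possible suboptimal routes).
    """
    if not path_set.paths:
        return SubnetworkView(
            main_nodes=frozenset(),
            unreachable=path_set.unreachable,
            path_highlights=[],
        )
    path_nodes = frozenset(n for path in path_set.paths for n in path)
    edges: dict[tuple[str, str], tuple[InteractionEvidence, ...]] = {}
    for a in path_nodes:
        for b in graph.adjacency(a) & path_nodes:
            if a < b:
                inter = graph.edge(a, b)
                edges[inter.pair] = inter.evidence
    mediators = _mediators(graph, path_nodes, excluded=path_nodes)
    for med, anchors in mediators.items():
        for a in anchors:
            inter = graph.edge(med, a)
            edges[inter.pair] = inter.evidence
    view = SubnetworkView(
        main_nodes=path_nodes,
        mediator_nodes=frozenset(mediators),
        edges=edges,
        display_edges=sorted(edges),
        path_highlights=[tuple(p) for p in path_set.paths],
    )
    return _styled(view)
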