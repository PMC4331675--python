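"""Serialize views and path sets into browser-viewable documents.

A :class:`ViewDocument` is the neutral, JSON-serializable description of a
network view: nodes with style classes and UniProt hyperlinks, display
links with evidence summaries, the full evidence table, and (for path
results) the list of shortest paths.  It can be

* rendered to a single self-contained HTML page (data embedded as JSON,
  force-directed layout done by a small bundled script) that works from a
  local file system or a cloud drive with no server;
* written/read as a JSON sidecar file;
* converted to/from a compact one-line text payload ("graph text") whose
  round trip is lossless for nodes, edges, directedness flags and styles —
  small enough to paste into an email or a messenger.

The graph-text grammar is versioned (``PPGT1``): three ``|``-separated
sections (format tag, nodes, edges); entries are ``;``-separated, fields
``,``-separated and percent-encoded, so any printable label survives.
"""

from __future__ import annotations

import json
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .graph import InteractionEvidence, PPIError
from .pathfind import PathSet
from .subnetwork import SubnetworkView

#: Default hyperlink template for a node's database entry.
UNIPROT_URL_TEMPLATE = "https://www.uniprot.org/uniprotkb/{accession}/entry"

GRAPH_TEXT_TAG = "PPGT1"


class GraphTextError(PPIError):
    """Corrupted graph-text payload; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class ViewNode:
    id: str
    label: str
    color: str = "blue"
    size: str = "large"
    href: str = ""


@dataclass(frozen=True)
class ViewLink:
    source: str
    target: str
    evidence_summary: str = ""
    directed: bool = False
    style: str = "solid"


@dataclass(frozen=True)
class EvidenceRow:
    acc_a: str
    acc_b: str
    source_db: str
    pubmed_ids: tuple[int, ...] = ()
    string_score: Optional[int] = None


@dataclass
class ViewDocument:
    nodes: list[ViewNode] = field(default_factory=list)
    links: list[ViewLink] = field(default_factory=list)
    tables: list[EvidenceRow] = field(default_factory=list)
    paths: Optional[list[tuple[str, ...]]] = None
    metadata: dict = field(default_factory=dict)


def summarize_evidence(evidence: tuple[InteractionEvidence, ...]) -> str:
    parts = []
    for ev in sorted(evidence, key=lambda e: e.sort_key()):
        if ev.string_score is not None:
            parts.append(f"{ev.source_db}(score:{ev.string_score})")
        elif ev.pubmed_ids:
            pm = ",".join(str(p) for p in sorted(ev.pubmed_ids))
            parts.append(f"{ev.source_db}(pubmed:{pm})")
        else:
            parts.append(ev.source_db)
    return "; ".join(parts)


def _evidence_rows(edges) -> list[EvidenceRow]:
    rows = []
    for pair in sorted(edges):
        for ev in edges[pair]:
            rows.append(
                EvidenceRow(
                    acc_a=pair[0],
                    acc_b=pair[1],
                    source_db=ev.source_db,
                    pubmed_ids=tuple(sorted(ev.pubmed_ids)),
                    string_score=ev.string_score,
                )
            )
    return rows


def to_view_document(
    view: Union[SubnetworkView, PathSet],
    display_names: Optional[dict[str, str]] = None,
    url_template: str = UNIPROT_URL_TEMPLATE,
    metadata: Optional[dict] = None,
) -> ViewDocument:
    """Build the export document for a subnetwork view or a path set.

    The paths section is present iff the input carries paths; display
    names default to the accession itself.
    """
    display_names = display_names or {}

    def node(acc: str, color: str, size: str) -> ViewNode:
        return ViewNode(
            id=acc,
            label=display_names.get(acc, acc),
            color=color,
            size=size,
            href=url_template.format(accession=acc),
        )

    if isinstance(view, PathSet):
        path_nodes = sorted({n for p in view.paths for n in p})
        endpoint = {view.source, view.target}
        nodes = [
            node(a, "blue" if a in endpoint else "green", "large" if a in endpoint else "small")
            for a in path_nodes
        ]
        links = [
            ViewLink(
                source=pair[0],
                target=pair[1],
                evidence_summary=summarize_evidence(evs),
            )
            for pair, evs in sorted(view.per_edge_evidence.items())
        ]
        return ViewDocument(
            nodes=nodes,
            links=links,
            tables=_evidence_rows(view.per_edge_evidence),
            paths=[tuple(p) for p in view.paths],
            metadata=dict(
                metadata
                or {
                    "source": view.source,
                    "target": view.target,
                    "total_cost": view.total_cost,
                    "by_step": view.by_step,
                    "truncated": view.truncated,
                    "unreachable": view.unreachable,
                }
            ),
        )

    nodes = [
        node(acc, *view.style.get(acc, ("green", "small")))
        for acc in sorted(view.nodes)
    ]
    links = [
        ViewLink(
            source=pair[0],
            target=pair[1],
            evidence_summary=summarize_evidence(view.edges[pair]),
        )
        for pair in view.display_edges
    ]
    return ViewDocument(
        nodes=nodes,
        links=links,
        tables=_evidence_rows(view.edges),
        paths=[tuple(p) for p in view.path_highlights]
        if view.path_highlights is not None
        else None,
        metadata=dict(metadata or {"sampled": view.sampled}),
    )


# ---------------------------------------------------------------------------
# JSON sidecar
# ---------------------------------------------------------------------------


def document_to_dict(doc: ViewDocument) -> dict:
    return {
        "nodes": [vars(n) for n in doc.nodes],
        "links": [vars(l) for l in doc.links],
        "tables": [
            {
                "acc_a": r.acc_a,
                "acc_b": r.acc_b,
                "source_db": r.source_db,
                "pubmed_ids": list(r.pubmed_ids),
                "string_score": r.string_score,
            }
            for r in doc.tables
        ],
        "paths": [list(p) for p in doc.paths] if doc.paths is not None else None,
        "metadata": doc.metadata,
    }


def document_from_dict(data: dict) -> ViewDocument:
    return ViewDocument(
        nodes=[ViewNode(**n) for n in data["nodes"]],
        links=[ViewLink(**l) for l in data["links"]],
        tables=[
            EvidenceRow(
                acc_a=r["acc_a"],
                acc_b=r["acc_b"],
                source_db=r["source_db"],
                pubmed_ids=tuple(r["pubmed_ids"]),
                string_score=r["string_score"],
            )
            for r in data["tables"]
        ],
        paths=[tuple(p) for p in data["paths"]] if data.get("paths") is not None else None,
        metadata=data.get("metadata", {}),
    )


def write_document_json(doc: ViewDocument, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(document_to_dict(doc), sort_keys=True, indent=1) + "\n",
        encoding="utf-8",
        newline="\n",
    )
    return path


def read_document_json(path: str | Path) -> ViewDocument:
    return document_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

_DATA_MARKER = 'id="network-data"'

_PAGE_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
svg {{ border: 1px solid #ccc; background: #fafafa; }}
circle.large {{ r: 14; }}
circle.small {{ r: 8; }}
circle.blue {{ fill: #4a7fd4; }}
circle.green {{ fill: #5cb85c; }}
line {{ stroke: #999; stroke-width: 1.5; }}
text {{ font-size: 11px; pointer-events: none; }}
table {{ border-collapse: collapse; margin-top: 1em; }}
td, th {{ border: 1px solid #ccc; padding: 2px 8px; font-size: 12px; }}
</style>
</head>
<body>
<h1>{title}</h1>
<svg id="network" width="760" height="560"></svg>
<div id="evidence"></div>
<script type="application/json" id="network-data">
{payload}
</script>
<script>
{script}
</script>
</body>
</html>
"""

# Self-contained force-directed renderer: spring forces along links,
# pairwise repulsion, mild centering; deterministic initial layout.
_RENDER_SCRIPT = """
(function () {
  var doc = JSON.parse(document.getElementById("network-data").textContent);
  var svg = document.getElementById("network");
  var W = svg.width.baseVal.value, H = svg.height.baseVal.value;
  var NS = "http://www.w3.org/2000/svg";
  var idx = {};
  doc.nodes.forEach(function (n, i) {
    idx[n.id] = i;
    var angle = (2 * Math.PI * i) / Math.max(doc.nodes.length, 1);
    n.x = W / 2 + (W / 3) * Math.cos(angle);
    n.y = H / 2 + (H / 3) * Math.sin(angle);
    n.vx = 0; n.vy = 0;
  });
  var lines = doc.links.map(function (l) {
    var el = document.createElementNS(NS, "line");
    svg.appendChild(el);
    return { el: el, s: idx[l.source], t: idx[l.target] };
  });
  var circles = doc.nodes.map(function (n) {
    var g = document.createElementNS(NS, "a");
    if (n.href) g.setAttribute("href", n.href);
    var c = document.createElementNS(NS, "circle");
    c.setAttribute("class", n.color + " " + n.size);
    c.setAttribute("r", n.size === "large" ? 14 : 8);
    var label = document.createElementNS(NS, "text");
    label.textContent = n.label;
    g.appendChild(c); g.appendChild(label); svg.appendChild(g);
    return { c: c, label: label };
  });
  function tick() {
    var i, j, a, b, dx, dy, d2, f;
    for (i = 0; i < doc.nodes.length; i++) {
      for (j = i + 1; j < doc.nodes.length; j++) {
        a = doc.nodes[i]; b = doc.nodes[j];
        dx = b.x - a.x; dy = b.y - a.y;
        d2 = dx * dx + dy * dy + 0.01;
        f = 2500 / d2;
        a.vx -= f * dx; a.vy -= f * dy; b.vx += f * dx; b.vy += f * dy;
      }
    }
    lines.forEach(function (l) {
      a = doc.nodes[l.s]; b = doc.nodes[l.t];
      dx = b.x - a.x; dy = b.y - a.y;
      var dist = Math.sqrt(dx * dx + dy * dy) + 0.01;
      f = 0.02 * (dist - 80) / dist;
      a.vx += f * dx; a.vy += f * dy; b.vx -= f * dx; b.vy -= f * dy;
    });
    doc.nodes.forEach(function (n) {
      n.vx += 0.005 * (W / 2 - n.x); n.vy += 0.005 * (H / 2 - n.y);
      n.vx *= 0.85; n.vy *= 0.85;
      n.x = Math.min(W - 15, Math.max(15, n.x + n.vx));
      n.y = Math.min(H - 15, Math.max(15, n.y + n.vy));
    });
    lines.forEach(function (l) {
      l.el.setAttribute("x1", doc.nodes[l.s].x);
      l.el.setAttribute("y1", doc.nodes[l.s].y);
      l.el.setAttribute("x2", doc.nodes[l.t].x);
      l.el.setAttribute("y2", doc.nodes[l.t].y);
    });
    doc.nodes.forEach(function (n, i) {
      circles[i].c.setAttribute("cx", n.x);
      circles[i].c.setAttribute("cy", n.y);
      circles[i].label.setAttribute("x", n.x + 10);
      circles[i].label.setAttribute("y", n.y - 10);
    });
  }
  var steps = 0;
  (function loop() { tick(); if (++steps < 300) requestAnimationFrame(loop); })();
  var tbl = ["<table><tr><th>Protein A</th><th>Protein B</th><th>Database</th>",
             "<th>PubMed IDs</th><th>STRING score</th></tr>"];
  doc.tables.forEach(function (r) {
    tbl.push("<tr><td>" + r.acc_a + "</td><td>" + r.acc_b + "</td><td>" +
             r.source_db + "</td><td>" + r.pubmed_ids.join(", ") + "</td><td>" +
             (r.string_score === null ? "" : r.string_score) + "</td></tr>");
  });
  tbl.push("</table>");
  document.getElementById("evidence").innerHTML = tbl.join("");
})();
"""


def render_html(doc: ViewDocument, out: str | Path, title: str = "PPI network view") -> Path:
    """Write a single self-contained HTML page for ``doc``.

    The document data is embedded verbatim as a JSON block, so it can be
    re-extracted from the page; rendering the same document twice yields
    byte-identical files.
    """
    out = Path(out)
    payload = json.dumps(document_to_dict(doc), sort_keys=True, separators=(",", ":"))
    # keep the payload safe inside a <script> block
    payload = payload.replace("</script", "<\\/script")
    html = _PAGE_TEMPLATE.format(title=title, payload=payload, script=_RENDER_SCRIPT)
    out.write_text(html, encoding="utf-8", newline="\n")
    return out


def extract_document(html_text: str) -> ViewDocument:
    """Recover the embedded :class:`ViewDocument` from a rendered page."""
    marker = html_text.index(_DATA_MARKER)
    start = html_text.index(">", marker) + 1
    end = html_text.index("</script>", start)
    payload = html_text[start:end].strip().replace("<\\/script", "</script")
    return document_from_dict(json.loads(payload))


# ---------------------------------------------------------------------------
# Reversible graph text ("share a graph via email")
# ---------------------------------------------------------------------------


def _q(s: str) -> str:
    return urllib.parse.quote(str(s), safe="")


def _uq(s: str) -> str:
    return urllib.parse.unquote(s)


def serialize_text(doc: ViewDocument) -> str:
    """One-line reversible encoding of the document's graph part.

    Nodes, edges, directedness flags and style classes survive the round
    trip exactly; the evidence table and paths are page content, not graph
    structure, and are not part of the editor text.
    """
    nodes = ";".join(
        ",".join([_q(n.id), _q(n.label), _q(n.color), _q(n.size), _q(n.href)])
        for n in doc.nodes
    )
    links = ";".join(
        ",".join(
            [
                _q(l.source),
                _q(l.target),
                "1" if l.directed else "0",
                _q(l.style),
                _q(l.evidence_summary),
            ]
        )
        for l in doc.links
    )
    return "|".join([GRAPH_TEXT_TAG, nodes, links])


def parse_text(payload: str) -> ViewDocument:
    """Decode a graph-text payload back into a :class:`ViewDocument`.

    Raises :class:`GraphTextError` with the character position on corrupt
    input.
    """
    if not payload.startswith(GRAPH_TEXT_TAG + "|"):
        raise GraphTextError(f"payload does not start with {GRAPH_TEXT_TAG!r}", 0)
    sections = payload.split("|")
    if len(sections) != 3:
        raise GraphTextError(
            f"expected 3 '|'-separated sections, found {len(sections)}",
            len(payload),
        )
    _, nodes_str, links_str = sections
    offset = len(GRAPH_TEXT_TAG) + 1

    nodes: list[ViewNode] = []
    if nodes_str:
        for entry in nodes_str.split(";"):
            fields = entry.split(",")
            if len(fields) != 5:
                raise GraphTextError(
                    f"node entry has {len(fields)} fields, expected 5", offset
                )
            nodes.append(
                ViewNode(
                    id=_uq(fields[0]),
                    label=_uq(fields[1]),
                    color=_uq(fields[2]),
                    size=_uq(fields[3]),
                    href=_uq(fields[4]),
                )
            )
            offset += len(entry) + 1

    offset = len(GRAPH_TEXT_TAG) + 1 + len(nodes_str) + 1
    links: list[ViewLink] = []
    node_ids = {n.id for n in nodes}
    if links_str:
        for entry in links_str.split(";"):
            fields = entry.split(",")
            if len(fields) != 5:
                raise GraphTextError(
                    f"edge entry has {len(fields)} fields, expected 5", offset
                )
            if fields[2] not in ("0", "1"):
                raise GraphTextError(
                    f"directedness flag must be 0 or 1, got {fields[2]!r}", offset
                )
            link = ViewLink(
                source=_uq(fields[0]),
                target=_uq(fields[1]),
                directed=fields[2] == "1",
                style=_uq(fields[3]),
                evidence_summary=_uq(fields[4]),
            )
            if link.source not in node_ids or link.target not in node_ids:
                raise GraphTextError(
                    f"edge endpoint missing from node list: {link.source},{link.target}",
                    offset,
                )
            links.append(link)
            offset += len(entry) + 1
    return ViewDocument(nodes=nodes, links=links)
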