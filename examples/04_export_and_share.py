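"""Export a view as a self-contained HTML page and as shareable text.

The HTML page embeds the network data plus a force-directed renderer, so
it opens from a local file or a cloud drive with no server.  The one-line
graph text is reversible — paste it into an email and the recipient can
reconstruct the exact same graph.
"""

import tempfile
from pathlib import Path

import ppipath as pp

work = Path(tempfile.mkdtemp())
bundle = pp.gen_random_ppi(12, 20, seed=7, out_dir=work / "fix")
graph = bundle.truth_graph
mapping = pp.build_mapping(bundle.mapping_path)

center = sorted(graph.nodes)[0]
view = pp.neighborhood_view(graph, center)
doc = pp.to_view_document(
    view, display_names={acc: mapping.display_name(acc) for acc in view.nodes}
)

page = pp.render_html(doc, work / "view.html", title=f"Neighborhood of {center}")
recovered = pp.extract_document(page.read_text())
print(f"wrote {page} ({page.stat().st_size} bytes)")
print(f"embedded data survives extraction: {recovered == doc}")

payload = pp.serialize_text(pp.ViewDocument(nodes=doc.nodes, links=doc.links))
print(f"graph text ({len(payload)} chars): {payload[:76]}...")
round_trip = pp.parse_text(payload)
print(f"text round trip lossless: "
      f"{round_trip.nodes == doc.nodes and round_trip.links == doc.links}")
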