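"""Build query-centric subnetwork views.

A 150-neighbor hub shows display sampling: the viewer draws a seeded
random 100 of the interactions while the evidence table keeps all 150.
A small multi-protein query shows the mediator rule: a non-query protein
joins the view only if it interacts with at least two main proteins.
"""

import tempfile

import ppipath as pp
from ppipath.formats import StandardRow, StandardTable
from ppipath.subnetwork import QueryProtein

hub = pp.gen_hub(150, seed=3, out_dir=tempfile.mkdtemp())
view = pp.neighborhood_view(hub.truth_graph, "HUB00", seed=0)
print(f"hub neighborhood: {len(view.edges)} interactions in the evidence table, "
      f"{len(view.display_edges)} drawn (sampled={view.sampled})")

pairs = [("A", "M"), ("B", "M"), ("A", "N"), ("A", "B"), ("B", "L"), ("L", "X")]
rows = [
    StandardRow(acc_a=min(a, b), acc_b=max(a, b), sources=frozenset({pp.PINA}),
                pubmed_ids=frozenset({30000000}))
    for a, b in pairs
]
g = pp.PPIGraph.from_table(StandardTable(rows=rows))
multi = pp.multi_view(
    g, [QueryProtein("A"), QueryProtein("B"), QueryProtein("L", is_main=False)]
)
print()
print(f"multi-protein view of A, B (main) and L (leaf):")
print(f"  mediators: {sorted(multi.mediator_nodes)}  "
      "(M touches both mains; N touches only A and X touches no main)")
print(f"  edges shown: {sorted(multi.edges)}")
print("  L-X is hidden: leaf nodes only show their interactions with mains.")
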