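# Methods

## The problem

Public PPI repositories disagree on format and identifier conventions:
curated MITAB-style tables (PINA-like, iRefIndex-like) reference proteins
by mixed identifier namespaces and attach PubMed evidence, while STRING
distributes `protein1 protein2 combined_score` links keyed by internal
Ensembl-protein IDs with an alias sidecar.  ppipath normalizes all of
these into one evidence-annotated undirected graph keyed by primary
UniProtKB accessions, then treats biological questions ("what interacts
with X?", "how can X reach Y?") as graph queries.

## Identifier mapping

The mapping input is a 5-column TSV (accession, reviewed flag, primary
gene name, `;`-joined synonyms, `;`-joined secondary accessions).  Lookup
is case-insensitive after whitespace trimming, because gene symbols are
case-ambiguous across sources; display names keep their original case.
Conflict resolution is deterministic and order-independent: an entry's
own primary accession always resolves to itself; otherwise a reviewed
(Swiss-Prot) claimant beats an unreviewed (TrEMBL) one; remaining ties go
to the lexicographically smaller accession.  The reviewed-then-
lexicographic tie-break is a design choice — reviewed entries are the
manually annotated section of UniProtKB and the more trustworthy claim on
a shared gene symbol, and the lexicographic fallback makes rebuilds
reproducible.  A failed lookup is a value (`None`), not an exception, so
callers implement the discard rule: interaction records with any
unmappable interactor are dropped and counted, never fatal.

## Parsing

The MITAB-like dialects vary in column layout, so parsers locate columns
by header name first (anything containing "interactor a/b", "uidA/uidB",
"pubmed"/"pmid"/"publication") and fall back to positions: interactors in
columns 0–1, PubMed IDs in column 2 (PINA-style) or column 7
(iRefIndex-style, 0-based).  Known identifier prefixes (`uniprotkb:`,
`refseq:`, `entrezgene/locuslink:`) are stripped; unknown prefixes pass
through verbatim for the mapping stage to resolve or discard.  Malformed
lines are skipped and counted — bulk downloads are dirty and a single bad
line must not abort a million-line import — but a file with zero
parseable lines is an error.  STRING parsing applies the confidence
threshold (default combined score 700, the conventional high-confidence
cut) *before* alias translation counts; rows whose internal IDs have no
alias are dropped and counted separately.

## Integration and overlap accounting

Within one source, duplicate pairs (including reversed duplicates — the
graph is undirected, pairs are stored lexicographically) merge by PubMed
union and score maximum.  Across sources, one row per unordered pair
records the union of supporting databases and PubMed IDs plus the STRING
score.  Overlap accounting mirrors the standard cross-database comparison
table: per database, the number of valid proteins (appearing in ≥ 1 kept
interaction — isolated proteins never occur in interaction downloads) and
interactions; for every database pair, the intersection size; and per
database, the count of items found nowhere else.  Self-interactions
(homodimers) are retained and counted.  Private data participates as one
more record set under any user-chosen source label.

## Edge-cost model

Curated evidence gives cost 1.  A STRING association with combined score
`S ∈ (0, 1000)` gives `max(1, log₁₀₀(1000 − S))`: score 900 maps to
exactly 1 (`log₁₀₀ 100 = 1`), lower confidence grows the cost smoothly to
≈ 1.5 near score 1, and the `max` clamps scores above 900 (where the raw
log dips below 1, reaching 0 at score 999).  Costs are therefore always
≥ 1, so every extra hop strictly lengthens a path.  When an edge carries
several evidence entries the **minimum** per-source cost governs: the
paper-trail default for curated edges stays 1 and the most favorable
evidence drives path search.  A user-assigned cost override (≥ 1) in the
standard TSV beats the computed value — the mechanism for manually
penalizing doubted interactions.  Score bounds are enforced (a score of
0 or ≥ 1000 is rejected rather than silently clamped).

One granularity note: the standard table stores each pair's PubMed IDs as
a single merged set, so when a graph is rebuilt from a combined TSV, both
curated evidence entries of a dual-curated edge carry the same merged
PMID set.  Per-database PMID attribution is preserved only upstream of
`combine`.

## All-shortest-paths search

A single-source Dijkstra run (binary heap, lazy deletion) records for
every node **all** predecessors whose relaxation ties the optimal
distance within an absolute tolerance of 1e-9 — summed float costs make
exact equality unreliable, and the tolerance is orders of magnitude below
any meaningful cost difference (the smallest nonzero cost gap in the
model at integer scores is ≈ 1e-3).  The predecessor relation is acyclic
because predecessors have strictly smaller distance (all edge costs ≥ 1),
so a backward depth-first walk from the target enumerates every distinct
shortest path.  Self-loops are ignored during search; they can never
shorten a route.  Step mode substitutes cost 1 per edge, making the run
equivalent to breadth-first search and the distances hop counts.

Enumerated paths are sorted fewest-steps-first, then lexicographically,
and truncated at a cap (default 100) with an explicit flag; the
deterministic order makes truncation reproducible.  The cap bounds the
output size — layered graphs show the number of co-optimal paths grows
multiplicatively — while distances remain exact regardless.  Single-source
screening runs Dijkstra once and enumerates per target, writing one
document per target plus an index so results can be browsed without
re-running the search.

Correctness is tested two independent ways: path sets against a
brute-force all-simple-paths oracle on every edge subset of a 4-node
graph and random 8-node graphs with random costs, and distances against
networkx's Dijkstra/BFS on larger random fixtures.

## Subnetwork views

Three builders share one output shape (main / input-leaf / mediator node
sets, full evidence-annotated edge set, ordered display edges, style
classes):

* **Neighborhood**: the query is the sole main node; when it has more
  than 100 interactions the display layer shows a seeded uniform random
  sample of exactly 100 (no sampling at exactly 100), while the evidence
  table always keeps everything.  The sampling RNG is seeded (default 0)
  so pages regenerate identically.
* **Multi-protein**: queries are designated main or leaf; all main–main
  edges appear, leaf edges only toward mains, and any non-query protein
  adjacent to **at least two** main proteins joins as a mediator with
  exactly its edges to mains — scaffold proteins often mediate what looks
  like a direct functional interaction.  Mediator–mediator edges are not
  drawn: mediators carry leaf semantics, and leaf semantics are
  main-edges-only.  Display sampling applies only in single-protein mode.
* **Path view**: nodes on any enumerated shortest path act as main nodes
  (mediators computed against the union of path nodes across all
  enumerated paths); per-path node sequences are kept so a selected table
  row can be highlighted.

Views are invariant to query order, and style is emitted as abstract
color/size classes; concrete pixels live in the export template so the
rendering style can be changed without touching view logic.

## Export

A view document carries nodes (with UniProtKB entry hyperlinks, template
configurable), display links with evidence summaries, the full evidence
table, optional path list and metadata.  HTML export embeds the document
as a JSON block beside a small self-written vanilla-JS force-directed
renderer (spring + repulsion + centering, fixed iteration budget) in a
single page, so output works from a local file system or a cloud drive
with no server; rendering is byte-deterministic and the embedded JSON is
re-extractable, which the tests exploit as a round-trip check.

The shareable graph text is a versioned one-line format:
`PPGT1|<nodes>|<edges>` with `;`-separated entries, `,`-separated
percent-encoded fields, and per-edge directedness flags and style
classes.  The round trip is lossless for the graph part (nodes, edges,
directedness, styles); evidence tables and path lists are page content,
not editable graph structure, and deliberately stay out of the payload.
Parse errors report the character position.

## Synthetic data

The fixture generators write the same dialects the parsers read, plus
independent bookkeeping from which ground truth (standard table, graph,
overlap summary) is built **without** going through the parsers, so
pipeline tests close the loop against a second code path.  `gen_random_ppi`
assigns each sampled pair a primary source from a configurable mix
(default uniform over the three databases) plus extra sources with
probability 0.25 each (producing overlaps), STRING scores uniform in
[700, 999], 1–3 fake PubMed IDs per curated line, and 5% decoy lines with
unmappable names to exercise the discard rule; STRING files list both
directions of every link, as real links files do.  Layered fixtures give
known path counts (product of interior widths); hub fixtures give known
degree structure for the sampling rule.

What the fixtures do **not** emulate: realistic degree distributions
(real PPI networks are heavy-tailed), organism-specific topology,
inter-database identifier noise beyond the synonym/secondary/decoy
scheme, or conflicting evidence for the same pair.  Passing tests
demonstrate the bookkeeping, cost model and algorithms are correct, not
that any biological conclusion transfers; headline counts from real 2014-
era database snapshots are inherently snapshot-dependent and are out of
scope.

Test and acceptance problem sizes (50-protein/120-edge integration
fixtures, 100 random views, exhaustive 4-node plus forty 8-node oracle
graphs, 50 step-mode fixtures) were chosen so the full suite runs in
seconds while every rule still triggers on non-trivial instances.

## Known limitations

* Interactions are undirected; directionality exists only as a display
  flag in the editor text, not in search.
* No organism filtering beyond what the alias/mapping files encode.
* The interactive browser editor (drag, restyle, local storage) is out of
  scope; only its reversible text serialization is implemented.
* Cost fusion across sources is limited to the min rule; no probabilistic
  combination of confidences.
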