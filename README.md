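# ppipath

Tools for building **personalized protein–protein interaction (PPI)
networks** from public database downloads and mining them for interaction
routes.  The package is aimed at molecular biologists and systems-biology
analysts who want to merge PPI evidence from curated repositories
(PINA-style and iRefIndex-style MITAB tables, with PubMed support) and
predicted associations (STRING links files with combined confidence
scores), then ask: *which proteins can interact with my protein of
interest, and through which chains of interactions can two proteins
communicate?*

## What it does

1. **Format** — parse the three download dialects into one standardized
   interaction TSV.  STRING rows below a confidence threshold
   (default combined score **700**) are dropped; internal `9606.ENSP…`
   IDs are translated through the alias file.
2. **Map** — resolve every gene name, synonym and secondary accession to
   a primary UniProtKB accession (Swiss-Prot entries win naming
   conflicts).  Proteins whose names cannot be mapped are discarded and
   counted.
3. **Combine** — merge sources per unordered protein pair, unioning
   PubMed evidence, and tally per-database valid proteins/interactions,
   all pairwise overlaps, and database-distinct items.
4. **Search** — enumerate **all** shortest interaction paths between two
   proteins, or from one protein to every other protein, under the cost
   model

   ```
   cost(edge) = 1                                  (PINA / iRefIndex evidence)
   cost(edge) = max(1, log₁₀₀(1000 − S))           (STRING combined score S)
   ```

   with multi-source edges taking the minimum and user overrides (≥ 1)
   winning outright.  `by_step=True` instead counts every edge as 1 and
   returns minimum-hop paths.
5. **View & export** — neighborhood, multi-protein (main/leaf/mediator)
   and path-centered subnetworks, rendered as self-contained HTML pages
   (embedded data + force-directed renderer, no server needed) or as a
   reversible one-line graph text that can be shared by email.

## Worked example

No downloads are needed to try the package: the `fixtures` module
generates all input dialects synthetically with known ground truth.
Running `python examples/01_integrate_databases.py` prints:

```
combined network: 50 proteins, 120 interactions
  PINA: 55 interactions, 2 records discarded as unmappable
  iRefIndex: 57 interactions, 3 records discarded as unmappable
  STRING: 63 interactions, 0 records discarded as unmappable

interaction overlap matrix:
           PINA  STRING  iRefIndex  Distinct
Database
PINA         55      19         21        19
STRING       19      63         19        29
iRefIndex    21      19         57        21
```

The diagonal is each database's own interaction count, off-diagonal cells
are pairwise overlaps, and *Distinct* counts interactions found in exactly
one database.  `python examples/02_shortest_paths.py` then enumerates all
six cost-3 routes through a layered test network:

```
6 shortest paths of total cost 3:
  L00N00 - L01N00 - L02N00 - L03N00
  ...
cost mode picks [('A', 'M', 'Z')] (total cost 2)
step mode picks [('A', 'Z')] (steps 1)
```

The same pipeline is scriptable from a shell:

```sh
ppipath --seed 7 --out-dir fix fixtures random --n-proteins 20 --n-edges 40
ppipath format pina --in fix/pina.tsv --mapping fix/mapping.tsv --out pina.std.tsv
ppipath format string --in fix/string_links.txt --alias fix/string_aliases.tsv \
        --mapping fix/mapping.tsv --out string.std.tsv
ppipath combine --in pina.std.tsv --in string.std.tsv \
        --out combined.tsv --report overlaps.tsv
ppipath path --graph combined.tsv --mapping fix/mapping.tsv --from GENE0 --to GENE5
ppipath view --graph combined.tsv --protein GENE0 --out view.json
ppipath export html --in view.json --out view.html
```

See `examples/` for one short narrative script per capability.

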