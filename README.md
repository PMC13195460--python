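# tpgraph

A toolkit for browsing and auditing **chemical transformation-product (TP)
data** as a directed reaction graph.  Environmental and metabolism studies
report reactions as *predecessor → successor* pairs (a parent compound and the
TP or metabolite it forms); community collections aggregate thousands of such
pairs from many datasets.  `tpgraph` ingests the two standard CSV tables of
such a collection (a compound-level table keyed by PubChem CID and a
reaction-level table of directed pairs with biosystem/enzyme/provenance
metadata), normalizes them, and turns them into a queryable directed
multigraph: compounds are nodes, every reaction row is a directed edge, and
parallel edges are kept as independent evidence for the same hop.

It is aimed at suspect- and nontarget-screening practitioners who need to

* trace **shortest directed pathways** between a parent and a TP (all
  equally short pathways are enumerated),
* explore a compound's **reaction neighborhood** (direct neighbors, the full
  ancestor or descendant closure, or its whole connected component),
* screen the compound set by **SMARTS substructure** (single patterns or
  batches),
* compute the collection's **statistics** (node roles, hub compounds,
  per-dataset unique reaction pairs, mass-difference distribution, multistep
  pathway depth), and
* export compound selections as **MetFrag** or **patRoon** suspect lists.

## The model

The collection is a directed multigraph `G = (V, E)` with `V` the set of
compounds (unique CIDs) and `E` the reaction rows; each edge `e = (u → v)`
carries its biosystem, enzyme, transformation label, `MassDiff = m(v) − m(u)`
(monoisotopic, Da), `XlogPDiff`, and dataset/evidence/source references.
Node roles partition `V`: a compound is a *predecessor only* (in-degree 0,
out-degree ≥ 1), *successor only*, *both*, or *isolated*.  Pathway queries
count reaction steps on the simple projection of `G` (parallel edges are one
step) and return **all** minimal-length directed simple paths.

Two normalization rules matter for display:

* **Consensus naming** — all names mentioned for a CID (compound-table names
  plus every predecessor/successor spelling in reaction rows) are tallied;
  the display name is the most frequent, with ties broken toward shorter
  names, then lexicographically.  Names longer than 100 characters or with
  more than 20 special characters are replaced by `CID <n>`.
* **Mass display filter** — reactions where a precursor lighter than 60 Da
  forms a product heavier than 300 Da (e.g. CO₂ → a coenzyme) are *hidden*
  from pathway and neighborhood displays: they are chemically real but act as
  hubs that spuriously bridge unrelated parts of the network.  The data is
  never modified, the hidden list is always reportable, and the filter can be
  disabled (`--no-filter`).

## Worked example

The package ships a seeded generator of synthetic tables in the source schema
(with a ground-truth ledger), so everything can be tried without a download:

```sh
tpgraph fixture --seed 7 --outdir tables
tpgraph ingest --compounds tables/compounds.csv --reactions tables/reactions.csv --out graph.json
```

prints (abridged):

```json
{"clean_fixes": 18, "skipped_compound_rows": 0, "skipped_reaction_rows": 0,
 "validation": {"n_nodes": 40, "n_edges": 72, "n_dangling": 0, "...": "..."}}
```

40 compounds and 72 reaction rows were loaded, 18 name spellings were cleaned
up, and validation found no edge with a missing endpoint.  Statistics:

```sh
tpgraph stats --graph graph.json --out stats.json
```

yields, among much else, `role_counts = {predecessor_only: 4, successor_only:
18, both: 17, isolated: 1}` (the four classes always sum to the node count),
the top hub compound with 19 distinct direct TPs, and the hidden-edge list —
here the two injected small→large reactions, e.g. `carbon dioxide → 6:2 FTOH`.
A pathway query:

```sh
tpgraph query path 1005 1040 --graph graph.json
```

```json
{"source": 1005, "target": 1040, "length": 3,
 "paths": [{"nodes": [1005, 1010, 1013, 1040],
            "hop_edge_ids": [[5, 6], [9], [41, 42]]}]}
```

one shortest pathway of 3 reaction steps; the first and last hops are each
backed by two parallel reaction records (the edge ids listed per hop).
Finally, a suspect-list export:

```sh
tpgraph export --graph graph.json --format metfrag --out suspects.csv
head -2 suspects.csv
```

```
Identifier,Name,InChIKey,InChI,SMILES,MolecularFormula,MonoisotopicMass
1001,carbon dioxide,CURLTUGMZLYLDI-UHFFFAOYSA-N,InChI=1S/CO2/c2-1-3,O=C=O,CO2,43.989829
```

The same operations are available as library functions (`tpgraph.ingest`,
`shortest_pathways`, `neighborhood`, `substructure_search`, `summary`,
`write_export`, ...).

To work with the real public collection, `tpgraph ingest --fetch-zenodo
10.5281/zenodo.17682349` downloads the pinned deposited tables and ingests
them identically; `--expected-nodes/--expected-edges --strict` verifies the
load against the release's published counts.

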