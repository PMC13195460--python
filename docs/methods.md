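# Methods

## Data model and ingestion

The toolkit consumes two CSV tables: a compound table (one row per CID, with
SMILES/InChI/InChIKey/IKFB, molecular formula, monoisotopic mass, XlogP,
IUPAC name and title) and a reaction table (one row per directed
predecessor → successor pair, with reaction SMILES, biosystem, enzyme, a
descriptive transformation label, mass and XlogP differences, and paired
dataset/evidence/source references).  Header matching is case-insensitive
against documented default spellings, with a per-field `column_map` override,
because deposited releases are not guaranteed to keep header capitalization
stable.  Loading is tolerant: rows without a parseable positive CID are
skipped and reported, never silently dropped, and unknown columns survive in
a passthrough field.  Duplicate reaction rows are kept verbatim — duplicates
across datasets are evidence, and any de-duplication is a query-time choice.

Graph assembly adds one node per compound row (duplicate CIDs are a hard
schema error, since the CID is the node key) and one edge per reaction row.
Edge ids are the 0-based row positions of the reaction table, which makes
builds byte-reproducible.  Edges naming a CID absent from the compound table
are quarantined into a dangling list that validation reports as "missing end
points"; self-loops are retained but flagged, on the principle that source
data is never silently altered.  `validate()` never raises — it reports
counts, the role-partition identity, dangling and self-loop edge ids,
mass-difference inconsistencies (|MassDiff − (m_succ − m_pred)| > 0.01 Da)
and optional expected-count/version mismatches; the CLI's `--strict` turns a
failed report into a non-zero exit.

## Consensus naming

Aggregated collections spell one compound many ways.  For each CID the name
multiset is the compound table's IUPAC name and title (once each) plus every
cleaned predecessor/successor spelling from reaction rows referencing it.
Cleaning is NFC Unicode normalization plus whitespace trimming/collapsing;
it is idempotent, and every fix is logged in an auditable report.  The
display name is chosen by majority vote: frequency descending, then length
ascending, then lexicographic.  Frequency leads because the vote is over
mentions across sources and reactions; length breaks ties toward short,
recognizable trade names; the lexicographic tail makes selection a pure
function of the multiset, independent of row order.  Winners longer than
100 characters or containing more than 20 special characters are replaced by
`CID <n>`.  "Special character" is deliberately simple: anything that is not
an ASCII letter, digit or space, so comma/hyphen-dense systematic names trip
the threshold as intended while `CID 123` itself (0 specials, short) is a
fixed point of the rule.

## Display filter

Reactions whose precursor is lighter than 60 Da and whose product is heavier
than 300 Da (strict inequalities; missing masses never hide an edge) are
excluded from pathway searches and neighborhood displays.  The thresholds
follow the published choice for this data: 60 Da excludes CO₂- and
acetate-like hub molecules while keeping small relevant precursors such as
triazole (69 Da); 300 Da spares ordinary transformations.  Hiding is purely
a view: `hidden_edges()` always reports the full list with endpoint names,
and every query accepts a disabled filter.

## Queries

Pathway search runs breadth-first on the simple projection of the visible
multigraph, so parallel edges count as one reaction step, and returns *all*
minimal-length simple node sequences (sorted for determinism) with every
parallel edge id attached per hop.  Equally short pathways through different
parallel edges are therefore one pathway with multiple evidence ids, not
separate pathways.  `source == target` returns a single zero-length path as
a harmless identity convention; an unreachable target returns an empty path
list with undefined length.  Neighborhood views: `direct` is distance 1 in
either direction with the focus's incident reactions; `predecessor_path` /
`successor_path` are BFS closures bounded by a depth limit (default 10 —
the traversals are depth-limited by design and the bound is configurable);
`all_connections` ignores the depth limit and returns the focus's weakly
connected component of the visible graph.  The explore view optionally
expands to siblings — compounds sharing a predecessor or successor with the
focus (distance 2 through a shared neighbor).  Identifier lookup is
case-insensitive exact match over CID, InChIKey, IKFB, SMILES, InChI and
every collected name; fuzzy matching and autocomplete are presentation
concerns and out of scope.  An optional biosystem restriction keeps only
compounds with at least one incident reaction recorded in that biosystem.

Substructure screening parses each compound's SMILES once per search and
tests every SMARTS pattern with RDKit; all patterns are validated before any
matching starts, unparseable compound SMILES are skipped with a report, and
a batch run is defined as — and tested to be — equivalent to the
corresponding single-pattern searches.  No fingerprint prescreen is used:
at the intended corpus size (thousands of compounds) a linear scan answers
in milliseconds.

## Statistics

* *Dataset uniqueness*: a directed CID pair is unique to a dataset when no
  other dataset contains it; the percentage divides unique distinct pairs by
  the dataset's raw row count.  Raw rows (not distinct pairs) are the
  denominator because within-dataset repeats genuinely dilute a dataset's
  unique contribution fraction.
* *Top compounds / hub thresholds* count distinct neighbor CIDs, not edges,
  so repeated evidence for one pair never inflates a hub.
* *Mass differences* are binned after rounding to 3 decimals (configurable)
  — coarse enough to merge float noise, fine enough to separate common
  biotransformations (oxygen addition +15.995 Da vs methylene +14.016 Da);
  each bin carries its most frequent transformation label.
* *Multistep statistics* run on the visible graph, consistent with the
  displays the filter governs.  Original predecessors are visible-graph
  source nodes (in-degree 0, out-degree > 0); a compound is multistep when
  its minimum directed distance from the nearest original predecessor is
  ≥ 2; its dataset span is the number of distinct dataset references over
  its entire visible ancestor subgraph, not only shortest paths — the
  cheapest definition consistent with "datasets included in the pathways",
  and the main place where a published aggregate could legitimately differ
  under another reading.

## Synthetic data

The fixture generator emulates the structural features of aggregated TP
collections that the toolkit must handle: cross-dataset duplicate pairs
(default rate 0.15 over 4 datasets), hub compounds (one out-hub with 12
distinct TPs and one in-hub with 11 distinct parents, so the ≥ 10-degree
statistics are exercised), multiple name spellings (20 % of reaction rows
use a variant), and 2 injected sub-60 Da → over-300 Da reactions for the
display filter.  Structures come from a fixed pool of 20 hand-checked SMILES
spanning aromatic/aliphatic and CF3/non-CF3 chemistry plus deliberately
small (CO₂, formaldehyde) and large (fluorotelomer alcohol, PFOA) molecules;
masses, formulas, InChIKeys and XlogP are derived from the structures with
RDKit, so MassDiff is always consistent with endpoint masses.  The default
table (40 compounds, ~70 reaction rows) is deliberately small: every
property the tests check is scale-free (partition identities, oracle
equivalences, byte determinism), so a larger table adds runtime without
adding evidence.  The generator's ledger (roles, per-dataset unique pairs,
probe path lengths, injected hidden edges) is computed with plain sets and a
hand-rolled BFS/DFS, independent of the graph machinery it is used to check.
What the fixtures do **not** emulate: realistic reaction chemistry, the
heavy-tailed degree distribution of real collections, or resolution of
names/SMILES to CIDs — passing tests certify the contracts, not chemical
realism.  Headline counts of the real deposited release are checked by a
separate end-to-end test that requires the two source CSVs locally (they are
fetched on demand when the host is reachable).

## Numerical and degenerate-input choices

Percentages: dataset uniqueness to 1 decimal, multistep dataset-span to a
whole percent.  Empty inputs are legal everywhere (empty tables → empty
graph → all-zero report; empty export → header-only file).  Ties break by
CID ascending (rankings), lexicographically (names, path enumeration
ordering).  All randomness lives in the fixture generator behind a single
seed; the pipeline proper is deterministic, and graph JSON caches are
written with sorted keys so reruns are byte-identical.

## Limitations

Contribution templates are accepted with placeholder CIDs; resolving names
or SMILES against an external registry is out of scope.  The graph is
in-memory and storage-agnostic — no server backend or transactional
updates.  Plot rendering is out of scope; the statistics report exposes the
underlying numbers (top bins, mass-vs-XlogP pairs) for external plotting.
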