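"""The directed reaction multigraph.

Every compound is a node (keyed by CID) and every reaction row becomes a
directed edge from predecessor to successor.  Parallel edges between the
same ordered pair are kept — they are alternative evidence for the same
hop (different biosystems, enzymes or references) — and are distinguished
by a stable integer edge id assigned from input row order, so two builds
of the same tables are identical.

Edges whose endpoints are missing from the compound table are quarantined
rather than dropped or fabricated; validation reports them as missing
end points.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

from .tables_io import CompoundRecord, ReactionRecord

__all__ = [
    "TransformationGraph",
    "NodeRole",
    "ValidationReport",
    "build_graph",
    "classify_roles",
    "degree_profile",
    "validate",
    "save_graph",
    "load_graph",
]

Role = Literal["predecessor_only", "successor_only", "both", "isolated"]


@dataclass
class TransformationGraph:
    """Directed multigraph over compounds, with quarantined dangling edges."""

    g: nx.MultiDiGraph
    compounds: dict[int, CompoundRecord]
    dangling: list[tuple[int, ReactionRecord]]  # (edge id, record)
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def reactions(self) -> list[tuple[int, ReactionRecord]]:
        """All (edge id, reaction) in edge-id order."""
        out = [(k, d["reaction"]) for _, _, k, d in self.g.edges(keys=True, data=True)]
        return sorted(out, key=lambda t: t[0])

    def reaction(self, edge_id: int) -> ReactionRecord:
        for u, v, k, d in self.g.edges(keys=True, data=True):
            if k == edge_id:
                return d["reaction"]
        raise KeyError(f"no edge with id {edge_id}")

    def datasets(self) -> list[str]:
        return sorted({r.datasetref for _, r in self.reactions() if r.datasetref})


@dataclass(frozen=True)
class NodeRole:
    cid: int
    role: Role


@dataclass
class ValidationReport:
    n_nodes: int
    n_edges: int
    n_dangling: int
    dangling_edge_ids: list[int]
    role_counts: dict[str, int]
    role_partition_ok: bool
    self_loop_edge_ids: list[int]
    mass_diff_flags: list[int]  # edge ids where mass_diff disagrees with endpoint masses
    expected_mismatches: list[str]
    version_ok: bool | None

    @property
    def ok(self) -> bool:
        return (
            self.n_dangling == 0
            and self.role_partition_ok
            and not self.mass_diff_flags
            and not self.expected_mismatches
            and self.version_ok in (None, True)
        )


def build_graph(
    compounds: Sequence[CompoundRecord],
    reactions: Sequence[ReactionRecord],
    meta: dict | None = None,
) -> TransformationGraph:
    """Assemble the multigraph from loaded (and normalized) tables.

    Duplicate CIDs in the compound table are a schema error: compound
    identifiers are the unique node keys.  Edge ids are the 0-based row
    positions of the reaction table, making builds reproducible.
    """
    seen: Counter = Counter(c.cid for c in compounds)
    dupes = sorted(cid for cid, n in seen.items() if n > 1)
    if dupes:
        raise ValueError(f"duplicate CIDs in compound table: {dupes[:10]}")
    by_cid = {c.cid: c for c in compounds}
    g = nx.MultiDiGraph()
    for c in compounds:
        g.add_node(c.cid, compound=c)
    dangling: list[tuple[int, ReactionRecord]] = []
    for eid, rxn in enumerate(reactions):
        if rxn.predecessor_cid in by_cid and rxn.successor_cid in by_cid:
            g.add_edge(rxn.predecessor_cid, rxn.successor_cid, key=eid, reaction=rxn)
        else:
            dangling.append((eid, rxn))
    tg = TransformationGraph(g, by_cid, dangling, dict(meta or {}))
    tg.meta.setdefault("datasets", tg.datasets())
    return tg


def classify_roles(graph: TransformationGraph) -> tuple[list[NodeRole], dict[str, int]]:
    """Partition nodes into predecessor-only / successor-only / both / isolated."""
    roles: list[NodeRole] = []
    counts = {"predecessor_only": 0, "successor_only": 0, "both": 0, "isolated": 0}
    g = graph.g
    for cid in g.nodes:
        ind, outd = g.in_degree(cid), g.out_degree(cid)
        if ind == 0 and outd == 0:
            role: Role = "isolated"
        elif ind == 0:
            role = "predecessor_only"
        elif outd == 0:
            role = "successor_only"
        else:
            role = "both"
        roles.append(NodeRole(cid, role))
        counts[role] += 1
    return roles, counts


def degree_profile(
    graph: TransformationGraph,
    direction: Literal["in", "out"],
    distinct: bool = True,
) -> dict[int, int]:
    """Per-node reaction counts.

    ``distinct=True`` counts distinct neighbor CIDs (unique reaction
    pairs); ``distinct=False`` counts edges, so parallel evidence for the
    same pair inflates the count.
    """
    g = graph.g
    out: dict[int, int] = {}
    for cid in g.nodes:
        if direction == "out":
            nbrs = g.successors(cid) if distinct else None
            out[cid] = len(set(nbrs)) if distinct else g.out_degree(cid)
        elif direction == "in":
            nbrs = g.predecessors(cid) if distinct else None
            out[cid] = len(set(nbrs)) if distinct else g.in_degree(cid)
        else:
            raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")
    return out


def validate(
    graph: TransformationGraph,
    expected_nodes: int | None = None,
    expected_edges: int | None = None,
    expected_version: str | None = None,
) -> ValidationReport:
    """Consistency report: counts, missing end points, roles, mass diffs.

    Never raises — callers decide what is fatal (e.g. strict ingest).
    """
    _, counts = classify_roles(graph)
    masses = {cid: c.exact_mass for cid, c in graph.compounds.items()}
    mass_flags = [
        eid for eid, rxn in graph.reactions()
        if rxn.mass_diff_consistent(masses) is False
    ]
    self_loops = [
        eid for eid, rxn in graph.reactions()
        if rxn.predecessor_cid == rxn.successor_cid
    ]
    mismatches = []
    if expected_nodes is not None and expected_nodes != graph.n_nodes:
        mismatches.append(f"node count: expected {expected_nodes}, got {graph.n_nodes}")
    if expected_edges is not None and expected_edges != graph.n_edges:
        mismatches.append(f"edge count: expected {expected_edges}, got {graph.n_edges}")
    version_ok = None
    if expected_version is not None:
        version_ok = graph.meta.get("version") == expected_version
    return ValidationReport(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        n_dangling=len(graph.dangling),
        dangling_edge_ids=[eid for eid, _ in graph.dangling],
        role_counts=counts,
        role_partition_ok=sum(counts.values()) == graph.n_nodes,
        self_loop_edge_ids=self_loops,
        mass_diff_flags=mass_flags,
        expected_mismatches=mismatches,
        version_ok=version_ok,
    )


# ---------------------------------------------------------------------------
# JSON node-link serialization (cache format; loading reproduces the graph
# exactly, including edge ids and quarantined dangling edges)
# ---------------------------------------------------------------------------

_COMPOUND_FIELDS = [f.name for f in dataclasses.fields(CompoundRecord)]
_REACTION_FIELDS = [f.name for f in dataclasses.fields(ReactionRecord)]


def _compound_to_dict(c: CompoundRecord) -> dict:
    d = {f: getattr(c, f) for f in _COMPOUND_FIELDS}
    d["names"] = dict(c.names)
    return d


def _compound_from_dict(d: dict) -> CompoundRecord:
    d = dict(d)
    d["names"] = Counter(d.get("names", {}))
    return CompoundRecord(**d)


def _reaction_to_dict(r: ReactionRecord) -> dict:
    return {f: getattr(r, f) for f in _REACTION_FIELDS}


def save_graph(graph: TransformationGraph, path: str | Path) -> None:
    payload = {
        "meta": graph.meta,
        "nodes": [_compound_to_dict(c) for c in
                  sorted(graph.compounds.values(), key=lambda c: c.cid)],
        "edges": [
            {"id": eid, **_reaction_to_dict(rxn)} for eid, rxn in graph.reactions()
        ],
        "dangling": [
            {"id": eid, **_reaction_to_dict(rxn)} for eid, rxn in graph.dangling
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=1, sort_keys=True, ensure_ascii=False),
        encoding="utf-8",
    )


def load_graph(path: str | Path) -> TransformationGraph:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    compounds = [_compound_from_dict(d) for d in payload["nodes"]]
    g = nx.MultiDiGraph()
    by_cid = {c.cid: c for c in compounds}
    for c in compounds:
        g.add_node(c.cid, compound=c)
    for e in payload["edges"]:
        eid = e.pop("id")
        rxn = ReactionRecord(**e)
        g.add_edge(rxn.predecessor_cid, rxn.successor_cid, key=eid, reaction=rxn)
    dangling = []
    for e in payload["dangling"]:
        eid = e.pop("id")
        dangling.append((eid, ReactionRecord(**e)))
    return TransformationGraph(g, by_cid, dangling, payload.get("meta", {}))
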