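"""Neighborhood, pathway and identifier queries over the reaction graph.

All display-facing traversals run on the *visible* graph: a mass-based
filter hides reactions in which a very small molecule (monoisotopic mass
below 60 Da, e.g. carbon dioxide or acetate) is recorded as the precursor
of a much larger one (above 300 Da).  Such reactions are chemically real
but act as data hubs that bridge otherwise unrelated regions of the
network and produce nonsensical "shortest" pathways.  The filter is a
display concern only: the underlying data is never modified, hidden
edges remain reportable, and filtering can be switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx

from .graphmodel import TransformationGraph

__all__ = [
    "EdgeFilter",
    "PathwayResult",
    "PathwayPath",
    "NeighborhoodView",
    "LookupResult",
    "hidden_edges",
    "visible_graph",
    "shortest_pathways",
    "neighborhood",
    "explore_tps",
    "lookup",
    "lookup_batch",
    "DEFAULT_DEPTH_LIMIT",
]

#: default traversal depth for predecessor/successor closure views
DEFAULT_DEPTH_LIMIT = 10


@dataclass(frozen=True)
class EdgeFilter:
    """Hide small-precursor -> large-successor reactions from displays.

    An edge is hidden iff the filter is enabled, the predecessor's exact
    mass is strictly below ``small_mass_max`` and the successor's exact
    mass is strictly above ``large_mass_min``.  Edges with either mass
    missing are never hidden.  The 60 Da floor excludes CO2/acetate-like
    hubs while keeping small but environmentally relevant precursors
    (e.g. triazole at 69 Da); the 300 Da ceiling spares ordinary
    transformations.
    """

    small_mass_max: float = 60.0
    large_mass_min: float = 300.0
    enabled: bool = True

    def __post_init__(self):
        if not self.small_mass_max < self.large_mass_min:
            raise ValueError(
                f"small_mass_max ({self.small_mass_max}) must be below "
                f"large_mass_min ({self.large_mass_min})"
            )

    def hides(self, predecessor_mass: float | None, successor_mass: float | None) -> bool:
        if not self.enabled or predecessor_mass is None or successor_mass is None:
            return False
        return predecessor_mass < self.small_mass_max and successor_mass > self.large_mass_min


@dataclass
class PathwayPath:
    """One shortest pathway: node sequence plus parallel edge ids per hop."""

    nodes: list[int]
    hop_edge_ids: list[list[int]]  # hop i connects nodes[i] -> nodes[i+1]


@dataclass
class PathwayResult:
    source_cid: int
    target_cid: int
    length: int | None  # reaction steps; None when no directed path exists
    paths: list[PathwayPath]
    filter_applied: EdgeFilter


@dataclass
class NeighborhoodView:
    focus_cid: int
    mode: str
    depth_limit: int | None
    nodes: set[int]
    edges: list[tuple[int, int, int]]  # (edge id, predecessor, successor)
    filter_applied: EdgeFilter


@dataclass
class LookupResult:
    query: str
    cids: list[int]

    @property
    def found(self) -> bool:
        return bool(self.cids)


def hidden_edges(
    graph: TransformationGraph, filt: EdgeFilter | None = None
) -> list[tuple[int, int, int, str, str]]:
    """Edges the mass filter would hide, with endpoint display names.

    Returns ``(edge id, predecessor cid, successor cid, predecessor name,
    successor name)`` tuples sorted by edge id.  Purely a report: the
    graph is untouched.
    """
    filt = filt if filt is not None else EdgeFilter()
    out = []
    for eid, rxn in graph.reactions():
        pred = graph.compounds[rxn.predecessor_cid]
        succ = graph.compounds[rxn.successor_cid]
        if filt.hides(pred.exact_mass, succ.exact_mass):
            out.append(
                (eid, pred.cid, succ.cid,
                 pred.display_name or pred.title, succ.display_name or succ.title)
            )
    return out


def visible_graph(
    graph: TransformationGraph, filt: EdgeFilter | None = None
) -> nx.MultiDiGraph:
    """The multigraph with hidden edges removed (a copy; source untouched)."""
    filt = filt if filt is not None else EdgeFilter()
    if not filt.enabled:
        return graph.g
    hidden = {eid for eid, *_ in hidden_edges(graph, filt)}
    if not hidden:
        return graph.g
    g = graph.g.copy()
    g.remove_edges_from(
        [(u, v, k) for u, v, k in graph.g.edges(keys=True) if k in hidden]
    )
    return g


def _simple_view(mg: nx.MultiDiGraph) -> nx.DiGraph:
    """Collapse parallel edges: one hop per ordered compound pair."""
    g = nx.DiGraph()
    g.add_nodes_from(mg.nodes)
    g.add_edges_from(mg.edges())
    return g


def _require_cid(graph: TransformationGraph, cid: int) -> None:
    if cid not in graph.g:
        raise KeyError(f"unknown compound identifier: CID {cid}")


def shortest_pathways(
    graph: TransformationGraph,
    source_cid: int,
    target_cid: int,
    filt: EdgeFilter | None = None,
) -> PathwayResult:
    """All minimal-step directed pathways from source to target.

    Steps are counted on the visible simple graph: parallel edges are one
    hop, with every parallel edge id attached to that hop.  All distinct
    minimal node sequences are returned.  ``source == target`` yields a
    single zero-length path; an unreachable target yields an empty result
    with ``length=None``.
    """
    filt = filt if filt is not None else EdgeFilter()
    _require_cid(graph, source_cid)
    _require_cid(graph, target_cid)
    if source_cid == target_cid:
        return PathwayResult(source_cid, target_cid, 0,
                             [PathwayPath([source_cid], [])], filt)
    mg = visible_graph(graph, filt)
    sg = _simple_view(mg)
    try:
        node_paths = sorted(nx.all_shortest_paths(sg, source_cid, target_cid))
    except nx.NetworkXNoPath:
        return PathwayResult(source_cid, target_cid, None, [], filt)
    paths = []
    for nodes in node_paths:
        hops = [
            sorted(mg[u][v].keys()) for u, v in zip(nodes, nodes[1:])
        ]
        paths.append(PathwayPath(list(nodes), hops))
    return PathwayResult(source_cid, target_cid, len(node_paths[0]) - 1, paths, filt)


Mode = Literal["direct", "predecessor_path", "successor_path", "all_connections"]


def _bounded_closure(sg: nx.DiGraph, focus: int, depth: int, reverse: bool) -> set[int]:
    g = sg.reverse(copy=False) if reverse else sg
    lengths = nx.single_source_shortest_path_length(g, focus, cutoff=depth)
    return set(lengths)


def neighborhood(
    graph: TransformationGraph,
    focus_cid: int,
    mode: Mode = "direct",
    depth_limit: int | None = DEFAULT_DEPTH_LIMIT,
    filt: EdgeFilter | None = None,
) -> NeighborhoodView:
    """Compound-page views: direct neighbors, ancestor/descendant closures,
    or the full weakly connected component, all over visible edges only.

    * ``direct`` — the focus plus every node one visible reaction away in
      either direction, with the reactions incident to the focus;
    * ``predecessor_path`` / ``successor_path`` — visible ancestors /
      descendants within ``depth_limit`` steps, with the induced edges;
    * ``all_connections`` — the focus's weakly connected component of the
      visible graph (``depth_limit`` is ignored).
    """
    filt = filt if filt is not None else EdgeFilter()
    _require_cid(graph, focus_cid)
    mg = visible_graph(graph, filt)
    sg = _simple_view(mg)
    depth = depth_limit if depth_limit is not None else DEFAULT_DEPTH_LIMIT
    if mode == "direct":
        nodes = {focus_cid} | set(sg.successors(focus_cid)) | set(sg.predecessors(focus_cid))
        edges = [
            (k, u, v)
            for u, v, k in mg.edges(keys=True)
            if focus_cid in (u, v)
        ]
    elif mode == "predecessor_path":
        nodes = _bounded_closure(sg, focus_cid, depth, reverse=True)
        edges = _induced_edges(mg, nodes)
    elif mode == "successor_path":
        nodes = _bounded_closure(sg, focus_cid, depth, reverse=False)
        edges = _induced_edges(mg, nodes)
    elif mode == "all_connections":
        nodes = nx.node_connected_component(sg.to_undirected(as_view=True), focus_cid)
        edges = _induced_edges(mg, nodes)
        depth = None
    else:
        raise ValueError(f"unknown neighborhood mode: {mode!r}")
    return NeighborhoodView(focus_cid, mode, depth, set(nodes),
                            sorted(edges), filt)


def _induced_edges(mg: nx.MultiDiGraph, nodes: set[int]) -> list[tuple[int, int, int]]:
    return [(k, u, v) for u, v, k in mg.edges(keys=True) if u in nodes and v in nodes]


def explore_tps(
    graph: TransformationGraph,
    focus_cid: int,
    include_siblings: bool = True,
    filt: EdgeFilter | None = None,
) -> NeighborhoodView:
    """The "explore all TPs" result set for one compound.

    Direct predecessors and successors of the focus, optionally expanded
    with sibling compounds that share a predecessor or a successor with
    it (distance 2 through a shared neighbor).
    """
    filt = filt if filt is not None else EdgeFilter()
    view = neighborhood(graph, focus_cid, "direct", filt=filt)
    if not include_siblings:
        return view
    mg = visible_graph(graph, filt)
    sg = _simple_view(mg)
    nodes = set(view.nodes)
    for pred in sg.predecessors(focus_cid):
        nodes |= set(sg.successors(pred))
    for succ in sg.successors(focus_cid):
        nodes |= set(sg.predecessors(succ))
    return NeighborhoodView(focus_cid, "explore_tps", 2, nodes,
                            _induced_edges(mg, nodes), filt)


# ---------------------------------------------------------------------------
# Identifier / name lookup
# ---------------------------------------------------------------------------


def _build_index(graph: TransformationGraph) -> dict[str, set[int]]:
    idx: dict[str, set[int]] = {}

    def add(key: str, cid: int) -> None:
        key = key.strip()
        if key:
            idx.setdefault(key.lower(), set()).add(cid)

    for cid, c in graph.compounds.items():
        add(str(cid), cid)
        add(f"cid {cid}", cid)
        add(c.inchikey, cid)
        add(c.ikfb, cid)
        add(c.smiles, cid)
        add(c.inchi, cid)
        add(c.display_name, cid)
        add(c.iupac_name, cid)
        add(c.title, cid)
        for name in c.names:
            add(name, cid)
    return idx


def lookup(
    graph: TransformationGraph,
    query: str,
    biosystem: str | None = None,
) -> LookupResult:
    """Exact-match lookup by CID, InChIKey, IKFB, SMILES, InChI or any
    collected name (case-insensitive).  Misses are reported, not raised.

    ``biosystem`` restricts hits to compounds with at least one incident
    visible-or-hidden reaction recorded in that biosystem.
    """
    idx = getattr(graph, "_lookup_index", None)
    if idx is None:
        idx = _build_index(graph)
        graph._lookup_index = idx  # cached; graph mutation would stale it
    cids = sorted(idx.get(query.strip().lower(), set()))
    if biosystem is not None:
        wanted = biosystem.strip().lower()
        keep = set()
        for _, rxn in graph.reactions():
            if rxn.biosystem.strip().lower() == wanted:
                keep.add(rxn.predecessor_cid)
                keep.add(rxn.successor_cid)
        cids = [c for c in cids if c in keep]
    return LookupResult(query, cids)


def lookup_batch(
    graph: TransformationGraph,
    lines: Iterable[str] | str | Path,
    biosystem: str | None = None,
) -> list[LookupResult]:
    """Batch lookup: one identifier per line; blank lines ignored.

    Accepts an iterable of lines or a path to a plain-text file.  Every
    non-blank line yields a result, hits and misses alike.
    """
    if isinstance(lines, (str, Path)):
        lines = Path(lines).read_text(encoding="utf-8").splitlines()
    return [lookup(graph, ln, biosystem) for ln in lines if ln.strip()]
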