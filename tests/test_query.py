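import itertools
import random

import pytest

import tpgraph as tp

from conftest import make_compound, make_reaction

NO_FILTER = tp.EdgeFilter(enabled=False)


def bruteforce_shortest(pairs, source, target):
    """All minimal-length simple node paths by exhaustive DFS enumeration."""
    adj = {}
    for p, s in set(pairs):
        adj.setdefault(p, set()).add(s)
    if source == target:
        return 0, [[source]]
    found = []

    def walk(path):
        for nxt in sorted(adj.get(path[-1], ())):
            if nxt in path:
                continue
            if nxt == target:
                found.append(path + [nxt])
            else:
                walk(path + [nxt])

    walk([source])
    if not found:
        return None, []
    best = min(len(p) for p in found) - 1
    return best, sorted(p for p in found if len(p) - 1 == best)


def random_digraph(rnd, max_nodes=12):
    n = rnd.randint(2, max_nodes)
    cids = list(range(1, n + 1))
    pairs = []
    for p, s in itertools.permutations(cids, 2):
        if rnd.random() < 0.2:
            pairs.append((p, s))
    return cids, pairs


class TestEdgeFilter:
    def test_thresholds_must_be_ordered(self):
        with pytest.raises(ValueError):
            tp.EdgeFilter(small_mass_max=300, large_mass_min=60)

    @pytest.mark.parametrize(
        "pred_mass, succ_mass, hidden",
        [
            (44.0, 364.0, True),     # CO2-like precursor of a large product
            (69.0, 350.0, False),    # triazole-sized precursors are retained
            (60.0, 301.0, False),    # boundary: strictly below 60 required
            (59.9, 300.0, False),    # boundary: strictly above 300 required
            (59.9, 300.1, True),
            (None, 400.0, False),    # missing masses never hide
            (44.0, None, False),
        ],
    )
    def test_predicate(self, pred_mass, succ_mass, hidden):
        assert tp.EdgeFilter().hides(pred_mass, succ_mass) is hidden

    def test_disabled_filter_hides_nothing(self):
        assert not tp.EdgeFilter(enabled=False).hides(10.0, 1000.0)


class TestHiddenEdges:
    def test_fixture_hidden_edges_match_ledger(self, graph, ledger):
        hidden = tp.hidden_edges(graph)
        assert [h[0] for h in hidden] == ledger["hidden_edge_ids"]
        # endpoint names are attached for the stats page listing
        assert all(h[3] and h[4] for h in hidden)

    def test_hidden_set_invariant_to_row_order(self, tables):
        compounds, reactions, _ = tables
        rnd = random.Random(5)
        shuffled = list(reactions)
        rnd.shuffle(shuffled)
        c1, _ = tp.collect_names([c for c in compounds], list(reactions))
        g1 = tp.build_graph(c1, list(reactions))
        g2 = tp.build_graph(c1, shuffled)
        pairs = lambda g: sorted((h[1], h[2]) for h in tp.hidden_edges(g))
        assert pairs(g1) == pairs(g2)

    def test_source_data_untouched(self, graph):
        before = graph.n_edges
        tp.hidden_edges(graph)
        tp.visible_graph(graph)
        assert graph.n_edges == before


class TestShortestPathways:
    def test_diamond_returns_both_paths(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2), (2, 4), (1, 3), (3, 4)])
        result = tp.shortest_pathways(g, 1, 4, NO_FILTER)
        assert result.length == 2
        assert sorted(p.nodes for p in result.paths) == [[1, 2, 4], [1, 3, 4]]

    def test_source_equals_target_is_zero_length(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2)])
        result = tp.shortest_pathways(g, 1, 1, NO_FILTER)
        assert result.length == 0
        assert [p.nodes for p in result.paths] == [[1]]

    def test_direction_is_respected(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2)])
        result = tp.shortest_pathways(g, 2, 1, NO_FILTER)
        assert result.length is None and result.paths == []

    def test_unknown_cid_is_a_lookup_error(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2)])
        with pytest.raises(KeyError, match="999"):
            tp.shortest_pathways(g, 1, 999)

    def test_parallel_edges_are_one_step_with_all_ids_attached(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2, "DS1"), (1, 2, "DS2"), (2, 3)])
        result = tp.shortest_pathways(g, 1, 3, NO_FILTER)
        assert result.length == 2
        (path,) = result.paths
        assert path.hop_edge_ids == [[0, 1], [2]]

    def test_fixture_probe_pairs_match_ledger(self, graph, ledger):
        for probe in ledger["probe_paths"]:
            result = tp.shortest_pathways(graph, probe["source"], probe["target"])
            assert result.length == probe["length"]
            assert len(result.paths) == probe["n_paths"]

    def test_matches_bruteforce_enumeration_on_random_graphs(self):
        rnd = random.Random(424242)
        for _ in range(60):
            cids, pairs = random_digraph(rnd)
            g = tp.build_graph(
                [make_compound(c) for c in cids],
                [make_reaction(p, s) for p, s in pairs],
            )
            src, tgt = rnd.choice(cids), rnd.choice(cids)
            want_len, want_paths = bruteforce_shortest(pairs, src, tgt)
            result = tp.shortest_pathways(g, src, tgt, NO_FILTER)
            assert result.length == want_len
            assert sorted(p.nodes for p in result.paths) == want_paths

    def test_filter_never_shortens_a_path(self, graph, ledger):
        filt = tp.EdgeFilter()
        for probe in ledger["probe_paths"]:
            unfiltered = tp.shortest_pathways(graph, probe["source"], probe["target"], NO_FILTER)
            filtered = tp.shortest_pathways(graph, probe["source"], probe["target"], filt)
            if unfiltered.length is None:
                assert filtered.length is None
            elif filtered.length is not None:
                assert filtered.length >= unfiltered.length


class TestNeighborhood:
    @pytest.fixture
    def chain(self, toy_graph_factory):
        return toy_graph_factory([(1, 2), (2, 3)])

    def test_predecessor_path_collects_ancestors(self, chain):
        view = tp.neighborhood(chain, 3, "predecessor_path", 10, NO_FILTER)
        assert view.nodes == {1, 2, 3}

    def test_direct_is_distance_one(self, chain):
        view = tp.neighborhood(chain, 3, "direct", filt=NO_FILTER)
        assert view.nodes == {2, 3}
        assert [(u, v) for _, u, v in view.edges] == [(2, 3)]

    def test_successor_path_respects_depth_limit(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2), (2, 3), (3, 4)])
        view = tp.neighborhood(g, 1, "successor_path", 2, NO_FILTER)
        assert view.nodes == {1, 2, 3}

    def test_all_connections_is_weak_component(self, toy_graph_factory):
        g = toy_graph_factory([(1, 2), (3, 2), (4, 5)])
        view = tp.neighborhood(g, 1, "all_connections", filt=NO_FILTER)
        assert view.nodes == {1, 2, 3}

    def test_hidden_bridge_splits_islands(self, toy_graph_factory):
        # islands {1,2} and {3,4} joined only by a small->large reaction
        g = toy_graph_factory(
            [(1, 2), (2, 3), (3, 4)],
            masses={1: 150.0, 2: 44.0, 3: 364.0, 4: 380.0},
        )
        visible = tp.neighborhood(g, 1, "all_connections", filt=tp.EdgeFilter())
        assert visible.nodes == {1, 2}
        unfiltered = tp.neighborhood(g, 1, "all_connections", filt=NO_FILTER)
        assert unfiltered.nodes == {1, 2, 3, 4}

    def test_direct_subset_of_all_connections(self, graph):
        for focus in list(graph.compounds)[::7]:
            direct = tp.neighborhood(graph, focus, "direct")
            full = tp.neighborhood(graph, focus, "all_connections")
            assert direct.nodes <= full.nodes

    def test_edges_stay_inside_subgraph(self, graph):
        for mode in ("direct", "predecessor_path", "successor_path", "all_connections"):
            view = tp.neighborhood(graph, list(graph.compounds)[10], mode)
            for _, u, v in view.edges:
                assert u in view.nodes and v in view.nodes


class TestExploreTps:
    def test_sibling_expansion_reaches_shared_neighbors(self, toy_graph_factory):
        # 1 and 3 share successor 2; 4 is unrelated
        g = toy_graph_factory([(1, 2), (3, 2), (4, 5)])
        base = tp.explore_tps(g, 1, include_siblings=False, filt=NO_FILTER)
        assert base.nodes == {1, 2}
        expanded = tp.explore_tps(g, 1, include_siblings=True, filt=NO_FILTER)
        assert expanded.nodes == {1, 2, 3}


class TestLookup:
    def test_lookup_by_collected_name(self, graph, ledger):
        name = ledger["names"]["1005"]
        result = tp.lookup(graph, name.upper())
        assert 1005 in result.cids

    def test_lookup_by_cid_inchikey_smiles(self, graph):
        comp = graph.compounds[1001]
        for key in (str(comp.cid), comp.inchikey, comp.ikfb, comp.smiles):
            assert comp.cid in tp.lookup(graph, key).cids

    def test_batch_reports_misses(self, graph, ledger, tmp_path):
        lines = [ledger["names"]["1001"], "definitely-not-a-compound", "1002"]
        path = tmp_path / "batch.txt"
        path.write_text("\n".join(lines))
        results = tp.lookup_batch(graph, path)
        assert len(results) == 3
        assert results[0].found and results[2].found
        assert not results[1].found

    def test_biosystem_filter_matches_linear_scan(self, graph):
        expected = set()
        for _, rxn in graph.reactions():
            if rxn.biosystem == "human":
                expected |= {rxn.predecessor_cid, rxn.successor_cid}
        for cid in list(graph.compounds)[:20]:
            hit = tp.lookup(graph, str(cid), biosystem="human")
            assert (cid in hit.cids) == (cid in expected)
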