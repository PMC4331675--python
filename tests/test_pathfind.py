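"""All-shortest-path search against brute-force and networkx oracles."""

import itertools
import random

import networkx as nx
import pytest

import ppipath as pp
from ppipath.formats import StandardRow, StandardTable
from ppipath.graph import COST_TOLERANCE


def graph_from_costs(edges):
    """Build a PPIGraph from {(a, b): cost} via cost overrides."""
    rows = [
        StandardRow(
            acc_a=min(a, b),
            acc_b=max(a, b),
            sources=frozenset({pp.PINA}),
            cost_override=float(cost),
        )
        for (a, b), cost in edges.items()
    ]
    return pp.PPIGraph.from_table(StandardTable(rows=rows))


def brute_force_shortest_paths(edges, source, target, tol=COST_TOLERANCE):
    """Independent oracle: enumerate every simple path by DFS, keep the
    cost-minimal ones."""
    adj = {}
    for (a, b), cost in edges.items():
        if a == b:
            continue
        adj.setdefault(a, {})[b] = cost
        adj.setdefault(b, {})[a] = cost
    found = []

    def dfs(node, path, cost):
        if node == target:
            found.append((cost, tuple(path)))
            return
        for nb, c in adj.get(node, {}).items():
            if nb not in path:
                dfs(nb, path + [nb], cost + c)

    if source in adj:
        dfs(source, [source], 0.0)
    if not found:
        return None, set()
    best = min(c for c, _ in found)
    return best, {p for c, p in found if abs(c - best) <= tol}


class TestDijkstraPredecessors:
    def test_direct_edge_beats_two_hop(self):
        g = graph_from_costs({("A", "B"): 1, ("B", "C"): 1, ("A", "C"): 1})
        dag = pp.dijkstra_predecessors(g, "A")
        assert dag.dist["C"] == 1.0
        assert dag.preds["C"] == {"A"}

    def test_square_tie_records_both_predecessors(self):
        g = graph_from_costs(
            {("A", "B"): 1, ("B", "D"): 1, ("A", "C"): 1, ("C", "D"): 1}
        )
        dag = pp.dijkstra_predecessors(g, "A")
        assert dag.preds["D"] == {"B", "C"}

    def test_unknown_source_raises_miss(self):
        g = graph_from_costs({("A", "B"): 1})
        with pytest.raises(pp.ProteinNotFound):
            pp.dijkstra_predecessors(g, "NOPE")

    def test_distances_match_networkx(self, random_bundle):
        """Cross-check against an independent library implementation."""
        g = random_bundle.truth_graph
        nxg = nx.Graph()
        for (a, b), inter in g.edges.items():
            if a != b:
                nxg.add_edge(a, b, weight=inter.cost)
        source = sorted(g.nodes)[0]
        dag = pp.dijkstra_predecessors(g, source)
        expected = nx.single_source_dijkstra_path_length(nxg, source)
        assert set(dag.dist) == set(expected)
        for node, dist in expected.items():
            assert dag.dist[node] == pytest.approx(dist, abs=1e-9)

    def test_triangle_inequality_on_fixture(self, random_bundle):
        g = random_bundle.truth_graph
        source = sorted(g.nodes)[0]
        dag = pp.dijkstra_predecessors(g, source)
        for (a, b), inter in g.edges.items():
            if a in dag.dist and b in dag.dist and a != b:
                assert dag.dist[b] <= dag.dist[a] + inter.cost + 1e-9
                assert dag.dist[a] <= dag.dist[b] + inter.cost + 1e-9

    def test_predecessor_relaxation_invariant(self, random_bundle):
        g = random_bundle.truth_graph
        source = sorted(g.nodes)[0]
        dag = pp.dijkstra_predecessors(g, source)
        assert dag.dist[source] == 0.0
        for v, preds in dag.preds.items():
            for p in preds:
                assert abs(dag.dist[p] + g.edge(p, v).cost - dag.dist[v]) <= 1e-9


class TestEnumerate:
    def test_layered_counts(self, layered_1321):
        g = layered_1321.truth_graph
        nodes = sorted(g.nodes)
        ps = pp.shortest_paths(g, nodes[0], nodes[-1])
        assert len(ps.paths) == 6
        assert not ps.truncated

    def test_cap_truncates_deterministically(self, tmp_path):
        # 3^5 = 243 shortest paths through five interior layers of width 3
        bundle = pp.gen_path_graph([1, 3, 3, 3, 3, 3, 1], seed=0, out_dir=tmp_path)
        g = bundle.truth_graph
        nodes = sorted(g.nodes)
        ps = pp.shortest_paths(g, nodes[0], nodes[-1], cap=100)
        assert len(ps.paths) == 100
        assert ps.truncated
        again = pp.shortest_paths(g, nodes[0], nodes[-1], cap=100)
        assert ps.paths == again.paths

    def test_paths_recost_to_dag_distance(self, random_bundle):
        g = random_bundle.truth_graph
        source = sorted(g.nodes)[0]
        results = pp.single_source(g, source)
        for target, ps in results.items():
            for path in ps.paths:
                recost = sum(g.edge(a, b).cost for a, b in zip(path, path[1:]))
                assert recost == pytest.approx(ps.total_cost, abs=1e-9)
                assert path[0] == source and path[-1] == target
                assert len(set(path)) == len(path)  # no repeated node

    def test_sort_order_fewest_steps_then_lexicographic(self):
        # two shortest routes of different step counts but equal cost
        g = graph_from_costs(
            {("A", "Z"): 2.0, ("A", "M"): 1.0, ("M", "Z"): 1.0}
        )
        ps = pp.shortest_paths(g, "A", "Z")
        assert ps.paths == [("A", "Z"), ("A", "M", "Z")]

    def test_unreachable_pair(self):
        g = graph_from_costs({("A", "B"): 1, ("C", "D"): 1})
        ps = pp.shortest_paths(g, "A", "D")
        assert ps.unreachable and not ps.paths

    def test_source_equals_target(self):
        g = graph_from_costs({("A", "B"): 1})
        ps = pp.shortest_paths(g, "A", "A")
        assert ps.paths == [("A",)]
        assert ps.total_cost == 0.0


class TestOracleEquivalence:
    def _check_all_pairs(self, edges):
        g = graph_from_costs(edges)
        nodes = sorted(g.nodes)
        for source in nodes:
            dag = pp.dijkstra_predecessors(g, source)
            for target in nodes:
                if target == source:
                    continue
                best, expected = brute_force_shortest_paths(edges, source, target)
                ps = pp.enumerate_paths(dag, target, cap=10_000)
                if best is None:
                    assert ps.unreachable
                else:
                    assert ps.total_cost == pytest.approx(best, abs=1e-9)
                    assert set(ps.paths) == expected

    def test_exhaustive_four_node_graphs(self):
        """Every edge subset of the complete 4-node graph, random costs."""
        nodes = ["A", "B", "C", "D"]
        all_edges = list(itertools.combinations(nodes, 2))
        rng = random.Random(1234)
        for mask in range(1, 2 ** len(all_edges)):
            edges = {
                e: rng.choice([1.0, 1.0, 1.5, 2.0, 3.0])
                for i, e in enumerate(all_edges)
                if mask >> i & 1
            }
            self._check_all_pairs(edges)

    def test_random_eight_node_graphs(self):
        """Random edge subsets of an 8-node pool with random costs."""
        nodes = [f"N{i}" for i in range(8)]
        all_edges = list(itertools.combinations(nodes, 2))
        rng = random.Random(99)
        for _ in range(60):
            k = rng.randint(4, 14)
            chosen = rng.sample(all_edges, k)
            edges = {e: rng.choice([1.0, 1.2386, 1.5, 2.0]) for e in chosen}
            self._check_all_pairs(edges)


class TestByStep:
    def test_hop_counts_equal_bfs_depth_on_random_fixtures(self, tmp_path):
        rng = random.Random(7)
        for trial in range(50):
            n = rng.randint(8, 16)
            m = rng.randint(n - 1, min(2 * n, n * (n - 1) // 2))
            bundle = pp.gen_random_ppi(
                n, m, seed=1000 + trial, out_dir=tmp_path / f"t{trial}"
            )
            g = bundle.truth_graph
            source = sorted(g.nodes)[0]
            dag = pp.dijkstra_predecessors(g, source, by_step=True)
            nxg = nx.Graph(
                (a, b) for (a, b) in g.edges if a != b
            )
            nxg.add_nodes_from(g.nodes)
            depth = nx.single_source_shortest_path_length(nxg, source)
            assert dag.dist == {k: float(v) for k, v in depth.items()}

    def test_cost_mode_and_step_mode_disagree_when_they_should(self):
        # 1-hop STRING edge (cost ~1.4) vs 3-hop curated route (cost 3):
        # cost mode picks the direct edge; step mode also picks it (1 step).
        # Conversely a 2-hop cost-2.0 route vs 1-hop cost-2.5 edge flips.
        g = graph_from_costs(
            {("A", "Z"): 2.5, ("A", "M"): 1.0, ("M", "Z"): 1.0}
        )
        cost_mode = pp.shortest_paths(g, "A", "Z")
        assert cost_mode.paths == [("A", "M", "Z")]
        step_mode = pp.shortest_paths(g, "A", "Z", by_step=True)
        assert step_mode.paths == [("A", "Z")]

    def test_by_step_string_edge_counts_one(self):
        # STRING score 700 gives cost ~1.2386; in step mode it counts 1
        row = StandardRow(
            acc_a="A", acc_b="B", sources=frozenset({pp.STRING}), string_score=700
        )
        g = pp.PPIGraph.from_table(StandardTable(rows=[row]))
        assert pp.shortest_paths(g, "A", "B", by_step=True).total_cost == 1.0


class TestSingleSource:
    def test_hub_center_screen(self, hub150):
        results = pp.single_source(hub150.truth_graph, "HUB00")
        assert len(results) == 150
        assert all(len(ps.paths) == 1 and ps.total_cost == 1.0 for ps in results.values())

    def test_hub_leaf_screen(self, hub150):
        results = pp.single_source(hub150.truth_graph, "LF00000")
        assert results["HUB00"].paths == [("LF00000", "HUB00")]
        others = [ps for t, ps in results.items() if t != "HUB00"]
        assert len(others) == 149
        assert all(
            len(ps.paths) == 1 and len(ps.paths[0]) == 3 for ps in others
        )

    def test_matches_pairwise_runs(self, random_bundle):
        g = random_bundle.truth_graph
        source = sorted(g.nodes)[0]
        screen = pp.single_source(g, source)
        for target in sorted(screen)[:10]:
            pairwise = pp.shortest_paths(g, source, target)
            assert screen[target].total_cost == pytest.approx(
                pairwise.total_cost, abs=1e-9
            )
            assert screen[target].paths == pairwise.paths


class TestNameResolution:
    def test_gene_names_resolve_through_mapping(self, random_bundle):
        mapping = pp.build_mapping(random_bundle.mapping_path)
        g = random_bundle.truth_graph
        acc_a, acc_b = sorted(g.nodes)[:2]
        name_a = mapping.display_name(acc_a)
        ps_by_name = pp.shortest_paths(g, name_a, acc_b, mapping=mapping)
        ps_by_acc = pp.shortest_paths(g, acc_a, acc_b, mapping=mapping)
        assert ps_by_name.paths == ps_by_acc.paths

    def test_unresolvable_name_names_the_failing_input(self, random_bundle):
        mapping = pp.build_mapping(random_bundle.mapping_path)
        g = random_bundle.truth_graph
        acc = sorted(g.nodes)[0]
        with pytest.raises(pp.ProteinNotFound, match="target"):
            pp.shortest_paths(g, acc, "NOSUCH", mapping=mapping)
        with pytest.raises(pp.ProteinNotFound, match="source"):
            pp.shortest_paths(g, "NOSUCH", acc, mapping=mapping)
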