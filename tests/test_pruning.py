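"""SPF and MFR pruning against exhaustive path/flow enumeration."""

import networkx as nx
import pytest

import glycokin as gk
from glycokin.network import StructuralError
from glycokin.pruning import prune_mfr, prune_spf

# Stable label -> LinearCode registry so the same abstract label receives the
# same structural identity in every test graph, and distinct labels differ.
_CODES: dict = {}


def _code_for(label) -> str:
    idx = _CODES.setdefault(str(label), len(_CODES) + 1)
    return "Ma2" * idx + "Mb4GNb4GN"


def _abstract_net(edges, source, sinks):
    """Build a ReactionNetwork with synthetic LinearCode labels per node."""
    nodes = sorted({n for e in edges for n in e[:2]}, key=str)
    codes = {n: _code_for(n) for n in nodes}
    return gk.build_network(
        [(u, v, "ManI") for u, v in edges], source, sinks, linear_codes=codes
    )


def _all_paths(net, source, sink):
    return list(nx.all_simple_paths(net.graph, source, sink))


class TestSPF:
    def test_diamond_keeps_both_shortest_paths(self):
        net = _abstract_net([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")], "A", ["D"])
        pruned = prune_spf(net)
        assert set(pruned.graph.nodes) == {"A", "B", "C", "D"}
        assert pruned.n_edges == 4

    def test_chain_is_returned_whole(self):
        net = _abstract_net([("A", "B"), ("B", "C")], "A", ["C"])
        pruned = prune_spf(net)
        assert set(pruned.graph.edges) == {("A", "B"), ("B", "C")}

    def test_longer_detour_excluded(self):
        net = _abstract_net(
            [("A", "B"), ("B", "C"), ("A", "X"), ("X", "Y"), ("Y", "C")], "A", ["C"]
        )
        pruned = prune_spf(net)
        assert set(pruned.graph.nodes) == {"A", "B", "C"}

    def test_equals_exhaustive_shortest_path_union(self):
        import numpy as np
        from conftest import random_dag

        rng = np.random.default_rng(42)
        for _ in range(25):
            graph = random_dag(rng, int(rng.integers(5, 11)))
            sinks = [n for n in graph.nodes if graph.out_degree(n) == 0]
            net = _abstract_net(list(graph.edges), 0, sinks)
            pruned = prune_spf(net)
            expected_nodes, expected_edges = {0}, set()
            for sink in sinks:
                paths = _all_paths(net, 0, sink)
                shortest = min(len(p) for p in paths)
                for p in paths:
                    if len(p) == shortest:
                        expected_nodes.update(p)
                        expected_edges.update(zip(p[:-1], p[1:]))
            assert set(pruned.graph.nodes) == expected_nodes
            assert set(pruned.graph.edges) == expected_edges

    def test_unreachable_sink_named_in_error(self):
        net = _abstract_net([("A", "B"), ("C", "D")], "A", ["B"])
        with pytest.raises(StructuralError, match="D"):
            prune_spf(net, "A", ["D"])

    def test_output_independent_of_node_labels(self, toy_net):
        tags = ["FA2G2S2", "FA4", "M5"]
        sinks = sorted(set().union(*(gk.tag_to_nodes(toy_net, t) for t in tags)))
        direct = prune_spf(toy_net, toy_net.source, sinks)
        relabeled = toy_net.copy()
        mapping = {n: f"node_{i}" for i, n in enumerate(sorted(toy_net.graph.nodes, reverse=True))}
        relabeled.graph = nx.relabel_nodes(relabeled.graph, mapping)
        relabeled.source = mapping[toy_net.source]
        relabeled.sinks = [mapping[s] for s in toy_net.sinks]
        pruned2 = prune_spf(relabeled, relabeled.source, [mapping[s] for s in sinks])
        codes = lambda net: {net.linear_code(n) for n in net.graph.nodes}
        assert codes(direct) == codes(pruned2)


class TestMFR:
    def test_diamond_minflow_keeps_exactly_one_branch(self):
        net = _abstract_net([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")], "A", ["D"])
        pruned = prune_mfr(net, mode="minflow")
        assert pruned.n_nodes == 3
        assert pruned.n_edges == 2
        # the surviving branch is one of the two feasible unit flows
        assert set(pruned.graph.edges) in (
            {("A", "B"), ("B", "D")},
            {("A", "C"), ("C", "D")},
        )

    def test_chain_returned_whole(self):
        net = _abstract_net([("A", "B"), ("B", "C")], "A", ["C"])
        pruned = prune_mfr(net)
        assert set(pruned.graph.edges) == {("A", "B"), ("B", "C")}

    def test_disjoint_sinks_force_both_branches(self):
        net = _abstract_net([("A", "B"), ("A", "C")], "A", ["B", "C"])
        pruned = prune_mfr(net)
        assert set(pruned.graph.edges) == {("A", "B"), ("A", "C")}

    def test_nested_sinks_on_a_chain_feasible(self):
        net = _abstract_net([("A", "B"), ("B", "C")], "A", ["B", "C"])
        pruned = prune_mfr(net)
        assert set(pruned.graph.edges) == {("A", "B"), ("B", "C")}

    def test_unreachable_sink_is_error(self):
        net = _abstract_net([("A", "B"), ("C", "D")], "A", ["B"])
        with pytest.raises(StructuralError):
            prune_mfr(net, "A", ["D"])

    def test_deterministic(self):
        net = _abstract_net(
            [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D"), ("D", "E")], "A", ["E"]
        )
        first = prune_mfr(net)
        for _ in range(3):
            assert set(prune_mfr(net).graph.edges) == set(first.graph.edges)

    def test_maxflow_mode_still_connects_all_sinks(self, toy_net):
        sinks = toy_net.sinks
        pruned = prune_mfr(toy_net, mode="maxflow")
        reachable = nx.descendants(pruned.graph, pruned.source) | {pruned.source}
        assert set(sinks) <= reachable


class TestPrunedInvariants:
    @pytest.mark.parametrize("method", ["spf", "mfr"])
    def test_dag_source_and_sinks(self, toy_net, method):
        prune = prune_spf if method == "spf" else prune_mfr
        pruned = prune(toy_net)
        assert nx.is_directed_acyclic_graph(pruned.graph)
        assert pruned.source in pruned.graph
        reachable = nx.descendants(pruned.graph, pruned.source) | {pruned.source}
        assert set(pruned.sinks) <= reachable

    def test_mfr_never_larger_than_spf_on_fixture(self, toy_net):
        spf = prune_spf(toy_net)
        mfr = prune_mfr(toy_net)
        assert mfr.n_edges <= spf.n_edges
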