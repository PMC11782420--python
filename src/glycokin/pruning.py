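"""Template-network pruning: shortest-path-finding (SPF) and minimum-flow
reachability (MFR) subgraph generation.

Both methods extract, from a large template GRN, a subgraph connecting the
biosynthetic source (M9, the species entering the cis Golgi) to every
experimentally observed sink:

* **SPF** unions *all* shortest source->sink paths (unit edge weights, so
  Dijkstra reduces to breadth-first search); the result is unique.
* **MFR** poses subgraph extraction as a single-commodity flow problem between
  artificial SuperSource/SuperSink nodes, with a lower bound of one flow unit
  on every sink's outflow arc so that each sink stays connected.  In
  ``minflow`` mode (default) the total flow routed over template edges is
  minimised, yielding the most parsimonious subgraph; ``maxflow`` mode
  maximises the circulated flow instead while honouring the same lower bounds.
"""

from __future__ import annotations

import networkx as nx

from .network import ReactionNetwork, StructuralError

__all__ = ["prune_spf", "prune_mfr"]

_SUPER_SOURCE = "__SuperSource__"
_SUPER_SINK = "__SuperSink__"


def _check_reachable(net: ReactionNetwork, source, sinks) -> None:
    reachable = nx.descendants(net.graph, source) | {source}
    for sink in sinks:
        if sink not in net.graph:
            raise StructuralError(f"sink {sink!r} not in template network")
        if sink not in reachable:
            raise StructuralError(
                f"sink {sink!r} unreachable from source {source!r} in template"
            )


def _induced(net: ReactionNetwork, nodes, edges, source, sinks) -> ReactionNetwork:
    sub = nx.DiGraph()
    for node in sorted(nodes):
        sub.add_node(node, **net.graph.nodes[node])
    for u, v in sorted(edges):
        sub.add_edge(u, v, **net.graph.edges[u, v])
    pruned = ReactionNetwork(sub, source, sorted(sinks))
    pruned.validate(pruned=True)
    return pruned


def prune_spf(net: ReactionNetwork, source=None, sinks=None) -> ReactionNetwork:
    """Union of all shortest source->sink paths, over every sink.

    Every biosynthetic step counts one, so all shortest paths per sink are
    enumerated under unit edge weights and combined; the union is unique and
    independent of iteration order.
    """
    source = net.source if source is None else source
    sinks = list(net.sinks if sinks is None else sinks)
    _check_reachable(net, source, sinks)

    nodes: set = {source}
    edges: set = set()
    for sink in sinks:
        for path in nx.all_shortest_paths(net.graph, source, sink):
            nodes.update(path)
            edges.update(zip(path[:-1], path[1:]))
    return _induced(net, nodes, edges, source, sinks)


def prune_mfr(
    net: ReactionNetwork,
    source=None,
    sinks=None,
    mode: str = "minflow",
    edge_capacity: int | None = None,
) -> ReactionNetwork:
    """Flow-based subgraph extraction guaranteeing each sink a unit of flow.

    A SuperSource feeds the biosynthetic source and every sink drains one
    mandatory flow unit into a SuperSink (lower bound 1, handled by the
    standard excess/deficit transformation).  Template edges default to a
    capacity equal to the number of sinks, so nested sinks sharing an upstream
    chain remain feasible; pass ``edge_capacity=1`` to force edge-disjoint
    routing.  ``minflow`` minimises total flow routed over template edges;
    ``maxflow`` maximises the total circulation under the same constraints.
    The returned subgraph is induced by the positive-flow edges plus the source
    and all sinks.
    """
    if mode not in ("minflow", "maxflow"):
        raise ValueError(f"mode must be 'minflow' or 'maxflow', got {mode!r}")
    source = net.source if source is None else source
    sinks = list(net.sinks if sinks is None else sinks)
    _check_reachable(net, source, sinks)

    n_sinks = len(sinks)
    cap = n_sinks if edge_capacity is None else int(edge_capacity)
    big = max(n_sinks, 1) * (net.n_edges + 1)

    flow_graph = nx.DiGraph()
    # deterministic construction order => deterministic network-simplex optimum
    for node in sorted(net.graph.nodes):
        flow_graph.add_node(node, demand=0)
    flow_graph.add_node(_SUPER_SOURCE, demand=0)
    flow_graph.add_node(_SUPER_SINK, demand=0)

    template_cost = 1 if mode == "minflow" else 0
    for u, v in sorted(net.graph.edges):
        flow_graph.add_edge(u, v, capacity=cap, weight=template_cost)
    flow_graph.add_edge(_SUPER_SOURCE, source, capacity=big, weight=0)
    for sink in sorted(sinks):
        # lower bound of 1 on sink -> SuperSink: pre-route one unit and
        # transfer it to the node demands (excess/deficit transformation)
        flow_graph.add_edge(sink, _SUPER_SINK, capacity=cap - 1, weight=0)
        flow_graph.nodes[sink]["demand"] += 1
        flow_graph.nodes[_SUPER_SINK]["demand"] -= 1
    return_cost = -1 if mode == "maxflow" else 0
    flow_graph.add_edge(_SUPER_SINK, _SUPER_SOURCE, capacity=big, weight=return_cost)

    try:
        flow = nx.min_cost_flow(flow_graph)
    except nx.NetworkXUnfeasible as exc:
        raise StructuralError(
            "minimum-flow lower bounds infeasible for sink set "
            f"{sinks}; a sink may be unreachable or the edge capacity too tight"
        ) from exc

    edges = {
        (u, v)
        for u, v in net.graph.edges
        if flow.get(u, {}).get(v, 0) > 0
    }
    nodes = {source, *sinks}
    for u, v in edges:
        nodes.update((u, v))
    return _induced(net, nodes, edges, source, sinks)
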