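"""Graph comparison and critical-node identification.

Pairwise network comparison covers node/edge overlap on LinearCode identity,
attribute-matched (sub)graph isomorphism and graph edit distance (GED, exact
for small graphs, anytime upper bound otherwise, normalised by the average
edge count of the pair).

Critical nodes — the anchors of the sequential parameter-estimation strategy —
are nodes that are simultaneously central intermediaries (betweenness
centrality above a percentile threshold) and key structural connectors
(membership in the dominance frontiers of other nodes above a percentile
threshold).  Both thresholds are strict (>), matching an "above 50th
percentile" reading at the default of 50.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import ReactionNetwork

__all__ = [
    "GraphComparison",
    "CriticalNodeReport",
    "compare_graphs",
    "dominance_frontiers",
    "df_membership",
    "identify_critical_nodes",
]

#: Exact GED search is attempted up to this many nodes; beyond it an anytime
#: upper-bound approximation with a wall-clock budget is used.
GED_EXACT_MAX_NODES = 12


@dataclass
class GraphComparison:
    """Pairwise structural comparison of two reaction networks."""

    node_overlap: int
    edge_overlap: int
    isomorphic: bool
    ged: float | None
    ged_exact: bool
    ged_normalized: float | None
    subgraph_1_of_2: bool
    subgraph_2_of_1: bool


@dataclass
class CriticalNodeReport:
    """Betweenness + dominance-frontier screening of a network."""

    betweenness: dict
    df_membership: dict
    critical_nodes: set
    critical_tags: list[str] = field(default_factory=list)


def _code_graph(net: ReactionNetwork) -> nx.DiGraph:
    """Relabel nodes to their LinearCode string (the structural identity)."""
    mapping = {n: net.linear_code(n) for n in net.graph.nodes}
    return nx.relabel_nodes(net.graph, mapping, copy=True)


def _node_match(a, b):
    return a.get("linear_code") == b.get("linear_code")


def _edge_match(a, b):
    return a.get("enzyme") == b.get("enzyme")


def _node_subst_cost(a, b):
    return 0.0 if a.get("linear_code") == b.get("linear_code") else 1.0


def _edge_subst_cost(a, b):
    return 0.0 if a.get("enzyme") == b.get("enzyme") else 1.0


def _unit_cost(_):
    return 1.0


def compare_graphs(
    net1: ReactionNetwork, net2: ReactionNetwork, ged_timeout: float = 30.0
) -> GraphComparison:
    """Compare two networks on LinearCode-labelled identity.

    GED uses unit insertion/deletion costs and zero substitution cost for
    matching LinearCode (nodes) / enzyme (edges) labels.  Above
    :data:`GED_EXACT_MAX_NODES` nodes the anytime search is stopped after
    ``ged_timeout`` seconds and the best bound found so far is reported with
    ``ged_exact=False``; if no bound was found within the budget, ``ged`` is
    ``None``.
    """
    g1, g2 = _code_graph(net1), _code_graph(net2)
    node_overlap = len(set(g1.nodes) & set(g2.nodes))
    edge_overlap = len(set(g1.edges) & set(g2.edges))

    isomorphic = nx.is_isomorphic(
        g1, g2, node_match=_node_match, edge_match=_edge_match
    )

    cost_kwargs = dict(
        node_subst_cost=_node_subst_cost,
        node_del_cost=_unit_cost,
        node_ins_cost=_unit_cost,
        edge_subst_cost=_edge_subst_cost,
        edge_del_cost=_unit_cost,
        edge_ins_cost=_unit_cost,
    )
    exact = max(g1.number_of_nodes(), g2.number_of_nodes()) <= GED_EXACT_MAX_NODES
    if exact:
        ged = nx.graph_edit_distance(g1, g2, **cost_kwargs)
    else:
        ged = None
        start = time.monotonic()
        for bound in nx.optimize_graph_edit_distance(g1, g2, **cost_kwargs):
            ged = bound
            if time.monotonic() - start > ged_timeout:
                break
        if ged is None:
            warnings.warn("GED search found no bound within the timeout", stacklevel=2)

    mean_edges = 0.5 * (g1.number_of_edges() + g2.number_of_edges())
    ged_normalized = None if ged is None or mean_edges == 0 else ged / mean_edges

    matcher_12 = nx.algorithms.isomorphism.DiGraphMatcher(
        g2, g1, node_match=_node_match, edge_match=_edge_match
    )
    matcher_21 = nx.algorithms.isomorphism.DiGraphMatcher(
        g1, g2, node_match=_node_match, edge_match=_edge_match
    )
    return GraphComparison(
        node_overlap=node_overlap,
        edge_overlap=edge_overlap,
        isomorphic=isomorphic,
        ged=ged,
        ged_exact=exact and ged is not None,
        ged_normalized=ged_normalized,
        subgraph_1_of_2=matcher_12.subgraph_is_monomorphic(),
        subgraph_2_of_1=matcher_21.subgraph_is_monomorphic(),
    )


def dominance_frontiers(net: ReactionNetwork, source=None) -> dict:
    """Dominance frontier DF(n) for every node reachable from the source.

    DF(n) is the set of nodes m such that n dominates a predecessor of m but
    does not strictly dominate m — the frontier at which n's dominance over
    source->m paths ends.  Unreachable nodes are excluded with a warning.
    """
    source = net.source if source is None else source
    reachable = nx.descendants(net.graph, source) | {source}
    if len(reachable) < net.n_nodes:
        excluded = sorted(set(net.graph.nodes) - reachable)
        warnings.warn(
            f"{len(excluded)} node(s) unreachable from {source!r} excluded: "
            f"{excluded}",
            stacklevel=2,
        )
    sub = net.graph.subgraph(reachable)
    return {n: set(frontier) for n, frontier in nx.dominance_frontiers(sub, source).items()}


def df_membership(frontiers: dict) -> dict:
    """Number of dominance-frontier sets each node belongs to."""
    membership = {n: 0 for n in frontiers}
    for frontier in frontiers.values():
        for member in frontier:
            membership[member] += 1
    return membership


def identify_critical_nodes(
    net: ReactionNetwork,
    source=None,
    betweenness_percentile: float = 50.0,
    df_percentile: float = 50.0,
) -> CriticalNodeReport:
    """Dual-criterion critical-node screen.

    A node is critical iff its betweenness centrality exceeds (strictly) the
    given percentile of betweenness over all reachable nodes AND its
    dominance-frontier membership count exceeds (strictly) the given
    percentile of membership counts.  Critical tags are ordered by BFS
    distance of each tag's nearest isomorph from the source (ties broken
    lexicographically); all structural isomorphs of a critical tag remain
    retrievable through :func:`glycokin.network.tag_to_nodes`.
    """
    source = net.source if source is None else source
    frontiers = dominance_frontiers(net, source)
    membership = df_membership(frontiers)
    reachable = set(frontiers)
    betweenness = nx.betweenness_centrality(net.graph.subgraph(reachable))

    bt_values = np.array([betweenness[n] for n in sorted(reachable)])
    mem_values = np.array([membership[n] for n in sorted(reachable)], dtype=float)
    bt_threshold = np.percentile(bt_values, betweenness_percentile)
    mem_threshold = np.percentile(mem_values, df_percentile)

    critical = {
        n
        for n in reachable
        if betweenness[n] > bt_threshold and membership[n] > mem_threshold
    }
    if not critical:
        warnings.warn(
            "no node passes both percentile thresholds; the estimation "
            "strategy degrades to a single stage",
            stacklevel=2,
        )

    distances = nx.single_source_shortest_path_length(net.graph, source)
    critical_tag_set = {net.tag(n) for n in critical}
    # order by the nearest isomorph of the tag anywhere in the network
    tag_distance: dict[str, float] = {}
    for node in reachable:
        tag = net.tag(node)
        if tag not in critical_tag_set:
            continue
        dist = distances.get(node, np.inf)
        if tag not in tag_distance or dist < tag_distance[tag]:
            tag_distance[tag] = dist
    critical_tags = sorted(tag_distance, key=lambda t: (tag_distance[t], t))

    return CriticalNodeReport(
        betweenness=betweenness,
        df_membership=membership,
        critical_nodes=critical,
        critical_tags=critical_tags,
    )
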