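"""Prune a template glycosylation reaction network to its observed sinks.

Sinks are the glycans observed above 1% relative abundance in any protein
entity.  SPF keeps the union of all shortest biosynthetic routes; MFR solves
a minimum-flow problem that guarantees every sink one unit of flow and is the
more parsimonious of the two.
"""

from glycokin import (
    compare_graphs,
    filter_observed_sinks,
    make_synthetic_profiles,
    make_toy_grn,
    prune_mfr,
    prune_spf,
    tag_to_nodes,
)

net = make_toy_grn()
profiles = make_synthetic_profiles(net, noise_sd=1.0, seed=0).table
tags = filter_observed_sinks(profiles, threshold_percent=1.0)
sinks = sorted(set().union(*(tag_to_nodes(net, t) for t in tags)) - {net.source})
print(f"observed tags >1%: {tags}")
print(f"template: {net.n_nodes} nodes / {net.n_edges} edges, {len(sinks)} sinks")

spf = prune_spf(net, net.source, sinks)
mfr = prune_mfr(net, net.source, sinks, mode="minflow")
print(f"SPF subgraph: {spf.n_nodes} nodes / {spf.n_edges} edges")
print(f"MFR subgraph: {mfr.n_nodes} nodes / {mfr.n_edges} edges")

cmp = compare_graphs(spf, mfr, ged_timeout=10.0)
print(
    f"overlap: {cmp.node_overlap} nodes / {cmp.edge_overlap} edges; "
    f"MFR subgraph of SPF: {cmp.subgraph_2_of_1}; "
    f"GED normalised by mean edge count: {cmp.ged_normalized:.2f}"
)
# Both pruned networks keep every observed species reachable from M9; the MFR
# one does it with the fewest biosynthetic routes.
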