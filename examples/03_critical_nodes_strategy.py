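"""Identify critical nodes and derive the sequential estimation strategy.

Critical nodes combine above-median betweenness centrality (central
intermediaries) with above-median dominance-frontier membership (convergence
points of alternative biosynthetic routes).  Each critical tag then anchors
one parameter-estimation stage; remaining enzymes form a final stage.
"""

from glycokin import (
    derive_strategy,
    identify_critical_nodes,
    make_synthetic_profiles,
    make_toy_grn,
)

net = make_toy_grn()
report = identify_critical_nodes(net)
print("critical tags (source -> sink order):", report.critical_tags)

profiles = make_synthetic_profiles(net, noise_sd=1.0, seed=0).table
plan = derive_strategy(net, report, profiles)
for stage in plan:
    tags = stage.critical_tags or ["<observed profile>"]
    target_igg = {t: round(p, 1) for t, p in sorted(stage.target_profile["IgG"].items())}
    print(f"stage {stage.stage_id}: enzymes {sorted(stage.enzymes)} -> target {tags}")
    print(f"   IgG stage target: {target_igg}")
# Stage targets keep the experimentally observed abundances of species
# upstream of the stage's critical nodes and accumulate everything else on
# the critical tag -- the profile a Golgi with downstream enzymes switched
# off would secrete.
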