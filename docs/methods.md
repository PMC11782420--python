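# Methods

This note documents the models and algorithms implemented in `glycokin`, the
defaults and units, the numerical choices, and what the synthetic fixtures do
and do not establish about real data.

## Glycan representation

Glycans are parsed from a LinearCode dialect restricted to the N-glycan
residues Man (`M`), GlcNAc (`GN`), Gal (`A`), Fuc (`F`), Neu5Ac (`NN`) and
Glc (`G`), with anomeric tokens `a`/`b` plus a linkage digit and branches in
parentheses; the reducing end is rightmost.  Tokenisation is greedy
(two-letter symbols first), branch nesting is validated, and the parse tree
is kept so that structural flags can be derived: a Fuc attached to the
reducing-end GlcNAc is core fucose; every GlcNAc beyond the two core
residues opens an antenna (bisecting GlcNAc and poly-LacNAc extension do not
occur in the pruned CHO networks this package targets, so no `B` tag part is
ever emitted and antenna counting by composition is exact).

Compositional tags follow the Oxford convention: `M<n>` for high-mannose,
`F?A<a>G<g>S<s>` for complex, `M<n>A<a>` for hybrid structures retaining
mannose, and `A0` for the trimmed Man3GlcNAc2 core (unambiguous, and it sorts
with the complex types).  The map LinearCode → tag is many-to-one;
`tag_to_nodes` returns all isomorphs of a tag in a network.  A syntactically
valid string whose composition is biosynthetically inconsistent (e.g. more
galactoses than antennae) parses but receives no tag.

## Network pruning

The template GRN is a DAG with enzyme-labelled edges; observed sinks are the
tags strictly above a threshold (default 1%) in *any* protein entity.

**SPF** unions all shortest source→sink paths under unit edge weights (every
biosynthetic step counts one, so Dijkstra reduces to BFS); the union is
unique and independent of iteration order.

**MFR** builds a flow network with a SuperSource feeding the source and every
sink draining into a SuperSink through an arc with a lower bound of one flow
unit (handled by the standard excess/deficit transformation).  In `minflow`
mode each unit of flow on a template edge costs 1 and the min-cost flow is
the most parsimonious subgraph meeting all lower bounds; `maxflow` mode
instead rewards circulation (cost −1 on the return arc) for a literal
maximum-flow reading.  Template edges default to capacity = number of sinks
rather than 1: with unit capacities the problem is infeasible whenever one
observed sink is an ancestor of another (all flow to the downstream sink must
transit the upstream sink's chain), which is the normal situation for
high-mannose sinks sitting on the single trimming chain.  The solver
(network simplex) is deterministic given the lexicographic construction
order used here.

**Comparison**: node/edge overlap is computed on LinearCode identity;
isomorphism and subgraph checks match node `linear_code` and edge `enzyme`
attributes.  The subgraph flags test subgraph *monomorphism* (edge
subgraph), since a pruned network is a subgraph of a larger one that has
extra edges among the same nodes.  GED uses unit insertion/deletion costs and
zero substitution cost on matching labels; it is exact up to 12 nodes and
otherwise an anytime upper bound under a wall-clock budget, reported with an
exactness flag and normalised by the average edge count of the pair.

## Critical nodes

A node is critical iff its betweenness centrality strictly exceeds the
configured percentile (default 50) of betweenness over reachable nodes *and*
its dominance-frontier membership count strictly exceeds the same percentile
of membership counts.  Dominance frontiers are computed from the dominator
tree rooted at the source; membership of *m* is the number of frontiers
containing *m* — in a DAG this counts convergence points of alternative
routes, complementing betweenness which favours early chain hubs.  Critical
tags are ordered by the BFS distance of each tag's nearest isomorph from the
source (ties lexicographic), which yields the biosynthetic ordering used by
the strategy.  If no node passes both thresholds the strategy degrades to a
single stage with all enzymes.

## Golgi kinetic model

The Golgi is four CSTRs in series (cis, medial, trans, TGN) under the
vesicular transport hypothesis.  For compartment c, entity p and species i
the steady-state balance is

    (1/τ_{c,p}) ([OS]_{i,c−1,p} − [OS]_{i,c,p}) + Σ_j S_ij r_j = 0,
    τ_{c,p} = τ_ref_c · MW_p / MW_ref,

with the stoichiometric matrix S holding one column per (edge, entity)
(substrate −1, product +1; entities never mix within a column).  The inlet to
the cis reactor splits each entity's production rate between M9 (fraction
`m9_prop`) and M8, the two species leaving the ER.  Enzyme levels are
distributed over compartments by per-enzyme localisation fractions
(glycosidases cis/medial-weighted, galactosyl- and sialyltransferases
trans/TGN-weighted; fully config-overridable); NSD concentrations are
compartment-constant by default but accept per-compartment values.

Rate laws are as printed in the README.  The competition sum defaults to all
alternative substrates of the enzyme across all entities
(`competition="all_substrates"`, the classical competitive-inhibition form);
`"entities_only"` restricts it to the same oligosaccharide on other entities,
the narrower reading of the model equations.  With a single entity the two
modes coincide on the substrate's own term.  Km is per (enzyme, entity) with
optional per-substrate overrides; kf and Kmd are per enzyme.  Units are µM,
minutes and kDa; profiles are percent.

Because transport is strictly feed-forward, the full system is block lower
triangular in the compartments and is solved as four successive root problems
(Powell hybrid, xtol 1e−12), each warm-started from the upstream state; the
result is identical to the simultaneous solve (verified by a species
permutation/relabelling test) at a fraction of the cost.  On failure the
solve retries along a geometric enzyme-scaling ladder (0.2→1.0 in five
steps, warm-started).  A run that still fails, or ends with concentrations
below −1e−7 µM, is returned flagged non-converged.  At a converged steady
state, per-entity outlet molar flow equals the production rate (mass
conservation) and tag-aggregated outlet profiles sum to 100%.

## Sequential ABC-SMC

Stages: one per critical tag in order, plus a final stage for remaining
enzymes.  A stage claims every enzyme on any simple path from the current
sources to the tag's isomorph nodes not claimed earlier (path enumeration
capped at 1e5 per pair); the critical nodes become the next sources.  The
stage target keeps the observed abundances of tags strictly preceding the
critical nodes (any isomorph an ancestor) and assigns the residual mass to
the critical tag(s), split equally when there are several — per protein
entity.  Each stage's forward model activates only the enzymes of the
current and earlier stages, so the residual genuinely accumulates on the
critical nodes; earlier-stage parameters are fixed at their MAP estimates.
Free parameters are attached to the stage owning their enzyme; entity-level
parameters (`m9_prop`) belong to stage 1.

ABC-SMC: generation 0 draws from independent uniform priors with equal
weights (ε₀ = ∞); each later generation sets ε to the weighted median
(weight-cumulative 50% point with linear interpolation) of the previous
distances, proposes by weight-proportional resampling plus a
multivariate-normal perturbation, rejects proposals outside the prior
support, accepts at distance ≤ ε until n particles, and re-weights by prior
density over the kernel mixture density.  The distance is the RMSE between
predicted and observed tag profiles on the percent scale, evaluated on the
observed support with missing predictions as 0 and both entities
concatenated.  Simulator failures reject the draw (counted, never fatal);
an acceptance stall ends the run with a warning.  All randomness flows from
one top-level seed (per-stage streams spawned via `SeedSequence`), so reruns
are bit-for-bit reproducible.

Two kernel covariances are distinguished deliberately.  The *transition*
kernel uses the full weighted sample covariance of the previous population —
the convention of multivariate-normal ABC transitions — because a
Silverman-shrunk kernel under-disperses proposals at small n and measurably
biases the posterior approximation.  Silverman's factor is retained where it
belongs, density estimation: the MAP estimate is the particle maximising the
weighted Gaussian-KDE density at particle locations.  Credible intervals are
weighted quantiles (2.5%/97.5%) whose interpolation reduces to numpy's
linear quantile for equal weights.

## Synthetic fixtures

The toy GRN (19 nodes, 22 edges, hand-authored LinearCode constants) encodes
mannose trimming M9→M8→M6→M5, the GnTI/ManI hybrid diamond converging on
M5A1, the fucosylation-order diamond (a6FucT before or after GnTII)
converging on FA2, arm-resolved FA2G1 and FA2G2S1 isomorph pairs converging
on FA2G2 and FA2G2S2, and divergent GnTIV/GnTV branches.  Those three
convergence points are exactly its critical tags, so the derived strategy has
four stages with enzyme sets {ManI, GnTI} / {ManII, GnTII, a6FucT} /
{b4GalT} / {GnTIV, GnTV, a3SiaT}.

Default conditions: entities IgG (150 kDa) and HCP (45 kDa) at equal
production rates of 0.1 µM/min; τ_ref = 5 min per compartment at
MW_ref = 150 kDa; turnover rates, enzyme levels, NSD pools and dissociation
constants at magnitudes typical of Golgi kinetic models, with HCP dissociation
constants one to two orders of magnitude above IgG's and
`m9_prop` = 0.20 (IgG) / 0.75 (HCP).  These conditions produce the
qualitative contrast of interest — FA2 above 50% on IgG, high-mannose above
98% on HCP — by the same mechanism offered for real CHO data: a lighter
entity transits faster and binds more weakly, so it matures less.

Synthetic glycoprofiles simulate the model at these parameters, drop tags
below a detection limit (default 0.1%, the analytical limit of
quantification; reporting dozens of exact zeros would be unrealistic, and
truncated noise on them would inject spurious mass), add truncated Gaussian
noise (default sd 1 percentage point) and renormalise to 100% per entity.

What passing tests on these fixtures do **not** show: real glycoprofiles
carry structured (non-Gaussian, correlated) measurement error; real GRNs are
an order of magnitude larger with genuinely unknown topology; and model error
dominates measurement error in real fits.  The fixtures establish the
correctness of the machinery (pruning oracles, conservation laws, posterior
recovery), not predictive validity for any cell line.

## Parameter-recovery experiment

The recovery benchmark frees one parameter of each class the estimation
workflow targets — `m9_prop:HCP`, `enz_total:ManI` and `km:ManI:HCP`, all
owned by stage 1 — under the workflow's uniform priors U(0.05, 0.95),
U(0.001, 35) µM and U(10, 10000) µM, at desk scale: population 50, 8
generations, 1% noise, 20 replicates (wall time well under a minute per
replicate on one CPU).  ε refinement stops at the known noise floor
(`eps_min` = noise sd): with a deterministic forward model, pushing ε below
the data's own discrepancy radius shrinks the acceptance region past the
statistically calibrated one and produces overconfident intervals.  Even so,
coverage of the 95% CrI at these scaled-down settings is marginal by
construction — the median-ε schedule lands near, not at, the calibrated
radius, and an enzyme level whose over-expression the data barely penalise
has an asymmetric posterior — so observed coverage sits around 85–90%
(18/20 at the seeds used in the tests) rather than the nominal 95%.
Parameters whose truth sits at the edge of a flat-likelihood plateau are
unsuitable for a coverage benchmark at all: the true posterior itself then
places less than 2.5% mass on one side of the truth.

## Known limitations

- Random-order Bi-Bi kinetics (relevant to a6FucT, GnTIII, a3SiaT in finer
  treatments) are not implemented; all glycosyltransferases use the
  sequential-order form.
- The GED cost model (unit costs, label-match substitution) is one of many;
  absolute GED values are not comparable across cost models, and beyond 12
  nodes only an upper bound is reported.
- Kinetic constants not under estimation are configuration values, not
  measurements; the defaults are field-typical magnitudes intended for the
  fixtures, and real applications should supply their own YAML config.
- O-glycans, site-specific glycosylation and dynamic (time-varying) culture
  coupling are out of scope.
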