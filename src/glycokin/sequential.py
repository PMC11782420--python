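"""Stage-wise sequential parameter estimation over a strategy plan.

Each stage runs ABC-SMC against its stage-specific target profile with a
forward model in which only the enzymes of the current and earlier stages are
active (downstream enzymes are absent, so abundance accumulates on the
stage's critical nodes exactly as the stage target assumes).  After a stage
finishes, its parameters are fixed to the MAP estimate for all subsequent
stages.  The final stage targets the original observed glycoprofile with the
full enzyme complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .kinetics import (
    GolgiModel,
    KineticParameterSet,
    apply_free_parameters,
    assemble_golgi_model,
    free_parameter_enzyme,
)
from .network import ReactionNetwork
from .smc import ParticlePopulation, PosteriorSummary, PriorSpec, abc_smc, summarize
from .strategy import StagePlan

__all__ = ["SequentialConfig", "StageResult", "assign_free_parameters", "run_sequential"]


@dataclass
class SequentialConfig:
    """ABC-SMC settings shared by every estimation stage."""

    n: int = 200
    max_generations: int = 25
    eps_min: float = 0.0
    seed: int = 0
    bw_factor: float = 1.0
    max_attempts_per_particle: int = 1000


@dataclass
class StageResult:
    stage: StagePlan
    populations: list  # list[ParticlePopulation]; empty when the stage had no free params
    summary: PosteriorSummary | None
    fixed_before: dict = field(default_factory=dict)  # MAP values seen by this stage


def assign_free_parameters(strategy: list, priors: dict) -> None:
    """Attach each free parameter to the stage owning its enzyme (in place).

    Enzyme-addressed parameters (``enz_total:*``, ``km:*:*``, ``kf:*``,
    ``kmd:*``) go to the stage whose enzyme set contains that enzyme;
    entity-level parameters (``m9_prop:*``, ``nsd_conc:*``) go to the first
    stage, where the Golgi-entry composition acts.
    """
    for stage in strategy:
        stage.free_parameters = []
    for name in priors:
        enzyme = free_parameter_enzyme(name)
        if enzyme is None:
            strategy[0].free_parameters.append(name)
            continue
        for stage in strategy:
            if enzyme in stage.enzymes:
                stage.free_parameters.append(name)
                break
        else:
            raise ValueError(f"parameter {name!r} refers to no stage enzyme")
    for stage in strategy:
        stage.free_parameters.sort()


def _active_submodel(
    net: ReactionNetwork,
    active_enzymes: set,
    model: GolgiModel,
) -> GolgiModel:
    """Model restricted to edges of active enzymes and nodes reachable from
    the Golgi inlet (M9 and M8); identical steady state for those species."""
    graph = nx.DiGraph()
    for node, data in net.graph.nodes(data=True):
        graph.add_node(node, **data)
    for u, v, data in net.graph.edges(data=True):
        if data["enzyme"] in active_enzymes:
            graph.add_edge(u, v, **data)
    roots = {net.source}
    if model.m8_node is not None:
        roots.add(model.m8_node)
    reachable = set()
    for root in roots:
        reachable |= nx.descendants(graph, root) | {root}
    sub = graph.subgraph(reachable).copy()
    sinks = sorted(n for n in sub.nodes if sub.out_degree(n) == 0)
    subnet = ReactionNetwork(sub, net.source, sinks)
    return assemble_golgi_model(
        subnet,
        model.entities,
        enzyme_specs=model.enzyme_specs,
        golgi_config=model.config,
        competition=model.competition,
    )


def run_sequential(
    model: GolgiModel,
    strategy: list,
    priors: dict,
    base_params: KineticParameterSet,
    config: SequentialConfig | None = None,
    simulate=None,
) -> list[StageResult]:
    """Run ABC-SMC stage by stage, fixing MAP estimates cumulatively.

    ``priors`` maps free-parameter names (see
    :func:`glycokin.kinetics.apply_free_parameters`) to uniform (lo, hi)
    bounds.  Returns one :class:`StageResult` per stage; stages without free
    parameters are recorded but not estimated.  Per-stage RNG streams are
    spawned deterministically from the top-level seed.
    """
    from .kinetics import simulate_golgi

    simulate = simulate or simulate_golgi
    config = config or SequentialConfig()
    assign_free_parameters(strategy, priors)
    stage_seeds = np.random.SeedSequence(config.seed).spawn(len(strategy))

    fixed: dict = {}
    active_enzymes: set = set()
    results: list[StageResult] = []
    for stage, seed_seq in zip(strategy, stage_seeds):
        active_enzymes |= stage.enzymes
        if not stage.free_parameters:
            results.append(
                StageResult(stage=stage, populations=[], summary=None,
                            fixed_before=dict(fixed))
            )
            continue
        stage_model = _active_submodel(model.net, active_enzymes, model)
        free_names = list(stage.free_parameters)
        prior = PriorSpec(names=free_names, bounds=[priors[n] for n in free_names])
        fixed_snapshot = dict(fixed)

        def simulator(theta, _model=stage_model, _names=free_names, _fixed=fixed_snapshot):
            values = dict(_fixed)
            values.update(zip(_names, theta))
            params = apply_free_parameters(base_params, values)
            try:
                result = simulate(_model, params)
            except (ValueError, FloatingPointError):
                return None
            if not result.converged:
                return None
            return result.profiles

        rng = np.random.default_rng(seed_seq)
        populations = abc_smc(
            prior,
            simulator,
            stage.target_profile,
            n=config.n,
            max_generations=config.max_generations,
            eps_min=config.eps_min,
            bw_factor=config.bw_factor,
            max_attempts_per_particle=config.max_attempts_per_particle,
            rng=rng,
        )
        if not populations or len(populations[-1].particles) == 0:
            raise RuntimeError(f"stage {stage.stage_id} returned an empty population")
        summary = summarize(populations[-1], config.bw_factor)
        fixed.update(zip(free_names, summary.map_estimate))
        results.append(
            StageResult(
                stage=stage,
                populations=populations,
                summary=summary,
                fixed_before=fixed_snapshot,
            )
        )
    if not any(r.summary is not None for r in results):
        warnings.warn("no stage carried free parameters; nothing estimated", stacklevel=2)
    return results
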