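"""Automated derivation of the sequential parameter-estimation strategy.

Given the ordered critical tags of a network, the strategy builds one
estimation stage per tag: the stage covers the graph segment between the
current source nodes and the tag's critical nodes, claims every enzyme that
appears on a simple source->critical path and has not been claimed by an
earlier stage, and receives a stage-specific target profile in which observed
tags preceding the critical nodes keep their experimental abundances while
the residual abundance accumulates on the critical tag(s) — reflecting a
Golgi in which downstream enzymes are not yet active.  After the last critical
tag, a final stage collects all remaining enzymes and targets the original
observed glycoprofile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .analysis import CriticalNodeReport
from .network import ReactionNetwork, tag_to_nodes

__all__ = [
    "StagePlan",
    "StrategyError",
    "derive_strategy",
    "stage_target_profile",
    "profiles_to_dict",
    "profiles_to_frame",
]

#: Simple-path enumeration cap per (source, critical) pair.
PATH_CAP = 100_000


class StrategyError(Exception):
    """Unreachable critical node or path-enumeration blowup."""


class DataError(ValueError):
    """Observed abundances inconsistent with the reallocation arithmetic."""


@dataclass
class StagePlan:
    """One estimation stage: graph segment, enzyme set and target profile."""

    stage_id: int
    source_nodes: set
    critical_nodes: set
    critical_tags: list[str]
    enzymes: set
    target_profile: dict  # entity -> {tag: percent}
    free_parameters: list = field(default_factory=list)


def profiles_to_dict(profiles) -> dict:
    """``entity -> {tag: percent}`` from a (entity, tag, percent) table."""
    if isinstance(profiles, dict):
        return {e: dict(tags) for e, tags in profiles.items()}
    out: dict[str, dict[str, float]] = {}
    for row in profiles.itertuples(index=False):
        out.setdefault(row.entity, {})[row.tag] = float(row.percent)
    return out


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    rows = [
        {"entity": entity, "tag": tag, "percent": pct}
        for entity in sorted(profiles)
        for tag, pct in sorted(profiles[entity].items())
    ]
    return pd.DataFrame(rows, columns=["entity", "tag", "percent"])


def _stage_target(
    net: ReactionNetwork, critical_nodes, critical_tags, observed: dict
) -> dict:
    """Step-3 reallocation, applied separately per protein entity."""
    ancestors: set = set()
    for node in critical_nodes:
        ancestors |= nx.ancestors(net.graph, node)
    preceding_tags = {net.tag(n) for n in ancestors}

    target: dict[str, dict[str, float]] = {}
    for entity, obs in observed.items():
        kept = {
            tag: pct
            for tag, pct in obs.items()
            if tag in preceding_tags and tag not in critical_tags
        }
        total_kept = sum(kept.values())
        if total_kept > 100.0 + 1e-6:
            raise DataError(
                f"preceding observed abundances sum to {total_kept:.3f}% > 100% "
                f"for entity {entity!r}"
            )
        residual = max(100.0 - total_kept, 0.0)
        share = residual / len(critical_tags)
        for tag in critical_tags:
            kept[tag] = share
        target[entity] = kept
    return target


def stage_target_profile(net: ReactionNetwork, stage: StagePlan, observed_profiles) -> dict:
    """Stage-specific target: preceding observed tags keep their experimental
    percentages, the residual mass goes to the stage's critical tag(s)."""
    observed = profiles_to_dict(observed_profiles)
    return _stage_target(net, stage.critical_nodes, stage.critical_tags, observed)


def derive_strategy(
    net: ReactionNetwork,
    critical_report: CriticalNodeReport,
    observed_profiles,
    path_cap: int = PATH_CAP,
) -> list[StagePlan]:
    """Build the ordered stage list (one per critical tag, plus a final stage).

    Stage k's enzymes are those appearing on any simple path from the current
    source nodes to the tag's critical nodes that were not claimed by an
    earlier stage; the critical nodes then become the sources of stage k+1.
    The final stage holds every remaining network enzyme and targets the
    original observed profile; it is emitted whenever remaining enzymes exist
    (and as the single stage when there are no critical tags at all).
    """
    observed = profiles_to_dict(observed_profiles)
    claimed: set = set()
    sources: set = {net.source}
    stages: list[StagePlan] = []

    for k, tag in enumerate(critical_report.critical_tags, start=1):
        critical_nodes = tag_to_nodes(net, tag)
        stage_enzymes: set = set()
        any_path = False
        for s in sorted(sources):
            for c in sorted(critical_nodes):
                count = 0
                for path in nx.all_simple_paths(net.graph, s, c):
                    count += 1
                    if count > path_cap:
                        raise StrategyError(
                            f"simple-path enumeration exceeded {path_cap} paths "
                            f"between {s!r} and {c!r}"
                        )
                    any_path = True
                    stage_enzymes.update(
                        net.graph.edges[u, v]["enzyme"]
                        for u, v in zip(path[:-1], path[1:])
                    )
        if not any_path:
            raise StrategyError(
                f"critical tag {tag!r} unreachable from stage sources {sorted(sources)}"
            )
        stage_enzymes -= claimed
        claimed |= stage_enzymes
        target = _stage_target(net, critical_nodes, [tag], observed)
        stages.append(
            StagePlan(
                stage_id=k,
                source_nodes=set(sources),
                critical_nodes=critical_nodes,
                critical_tags=[tag],
                enzymes=stage_enzymes,
                target_profile=target,
            )
        )
        sources = set(critical_nodes)

    remaining = net.enzymes() - claimed
    if remaining or not stages:
        stages.append(
            StagePlan(
                stage_id=len(stages) + 1,
                source_nodes=set(sources),
                critical_nodes=set(),
                critical_tags=[],
                enzymes=remaining,
                target_profile={e: dict(t) for e, t in observed.items()},
            )
        )
    return stages
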