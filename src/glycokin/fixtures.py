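"""Synthetic reaction networks and glycoprofiles.

The toy GRN is a hand-authored, biosynthetically sensible 19-node N-glycan
network for CHO-like cells: mannose trimming from M9, GnTI/GnTII antenna
construction with the fucosylation-order diamond (fucosylate before or after
GnTII), arm-resolved galactosylation and sialylation isomorph pairs, and
divergent GnTIV/GnTV branching.  Its convergence points are M5A1, FA2 and
FA2G2, so the dual betweenness/dominance-frontier criterion recovers exactly
those critical tags and the derived estimation strategy has four stages with
enzyme sets {ManI, GnTI} / {ManII, GnTII, a6FucT} / {b4GalT} /
{GnTIV, GnTV, a3SiaT}.

Synthetic glycoprofiles are produced by simulating the Golgi model at a known
parameter set (theta*) and perturbing tag percentages with truncated Gaussian
noise; the default conditions emulate the qualitative contrast between a
heavy, high-affinity entity processed to core-fucosylated biantennary
structures ("IgG") and a light, low-affinity entity retaining high-mannose
structures ("HCP").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import (
    GolgiConfig,
    KineticParameterSet,
    ProteinEntity,
    SimulationResult,
    assemble_golgi_model,
    simulate_golgi,
)
from .network import ReactionNetwork, build_network

__all__ = [
    "FixtureSpec",
    "SyntheticProfiles",
    "TOY_LINEAR_CODES",
    "make_toy_grn",
    "default_entities",
    "default_parameters",
    "make_synthetic_profiles",
]

#: Hand-authored LinearCode constants for the toy network (id -> code).
TOY_LINEAR_CODES = {
    "M9": "Ma2Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
    "M8": "Ma2Ma3(Ma2Ma3(Ma2Ma6)Ma6)Mb4GNb4GN",
    "M6": "Ma3(Ma2Ma3(Ma6)Ma6)Mb4GNb4GN",
    "M5": "Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN",
    "M6A1": "GNb2Ma3(Ma2Ma3(Ma6)Ma6)Mb4GNb4GN",
    "M5A1": "GNb2Ma3(Ma3(Ma6)Ma6)Mb4GNb4GN",
    "M4A1": "GNb2Ma3(Ma6Ma6)Mb4GNb4GN",
    "A1": "GNb2Ma3(Ma6)Mb4GNb4GN",
    "A2": "GNb2Ma3(GNb2Ma6)Mb4GNb4GN",
    "FA1": "GNb2Ma3(Ma6)Mb4GNb4(Fa6)GN",
    "FA2": "GNb2Ma3(GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G1a": "Ab4GNb2Ma3(GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G1b": "GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G2": "Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G2S1a": "NNa3Ab4GNb2Ma3(Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G2S1b": "Ab4GNb2Ma3(NNa3Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA2G2S2": "NNa3Ab4GNb2Ma3(NNa3Ab4GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA3": "GNb4(GNb2)Ma3(GNb2Ma6)Mb4GNb4(Fa6)GN",
    "FA4": "GNb4(GNb2)Ma3(GNb6(GNb2)Ma6)Mb4GNb4(Fa6)GN",
}

_TOY_EDGES = [
    ("M9", "M8", "ManI"),
    ("M8", "M6", "ManI"),
    ("M6", "M5", "ManI"),
    ("M6", "M6A1", "GnTI"),
    ("M5", "M5A1", "GnTI"),
    ("M6A1", "M5A1", "ManI"),
    ("M5A1", "M4A1", "ManII"),
    ("M4A1", "A1", "ManII"),
    ("A1", "A2", "GnTII"),
    ("A1", "FA1", "a6FucT"),
    ("A2", "FA2", "a6FucT"),
    ("FA1", "FA2", "GnTII"),
    ("FA2", "FA2G1a", "b4GalT"),
    ("FA2", "FA2G1b", "b4GalT"),
    ("FA2G1a", "FA2G2", "b4GalT"),
    ("FA2G1b", "FA2G2", "b4GalT"),
    ("FA2", "FA3", "GnTIV"),
    ("FA3", "FA4", "GnTV"),
    ("FA2G2", "FA2G2S1a", "a3SiaT"),
    ("FA2G2", "FA2G2S1b", "a3SiaT"),
    ("FA2G2S1a", "FA2G2S2", "a3SiaT"),
    ("FA2G2S1b", "FA2G2S2", "a3SiaT"),
]


@dataclass
class FixtureSpec:
    """Configuration of the toy-network generator."""

    name: str = "default"
    n_isomorph_pairs: int = 2  # 0: none, 1: FA2G1 pair, 2: + FA2G2S1 pair
    enzymes: tuple | None = None  # restrict the edge set to this enzyme subset
    sinks: tuple | None = None  # requested sinks (default: leaves)
    seed: int = 0
    noise_sd: float = 1.0  # percent units


@dataclass
class SyntheticProfiles:
    """Glycoprofile table plus the ground truth that generated it."""

    table: pd.DataFrame  # entity, tag, percent
    theta_star: KineticParameterSet
    result: SimulationResult


def make_toy_grn(spec: FixtureSpec | None = None) -> ReactionNetwork:
    """Build the toy GRN; deterministic, always a valid DAG with M9 source."""
    spec = spec or FixtureSpec()
    drop: set = set()
    if spec.n_isomorph_pairs < 2:
        drop |= {"FA2G2S1b"}
    if spec.n_isomorph_pairs < 1:
        drop |= {"FA2G1b"}
    edges = [
        (u, v, e)
        for u, v, e in _TOY_EDGES
        if u not in drop and v not in drop
        and (spec.enzymes is None or e in spec.enzymes)
    ]
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_edges_from((u, v) for u, v, _ in edges)
    if "M9" not in graph:
        raise ValueError("enzyme subset removes the M9 source from the network")
    reachable = nx.descendants(graph, "M9") | {"M9"}
    edges = [(u, v, e) for u, v, e in edges if u in reachable and v in reachable]
    sinks = spec.sinks
    if sinks is None:
        kept = nx.DiGraph()
        kept.add_edges_from((u, v) for u, v, _ in edges)
        sinks = tuple(sorted(n for n in kept.nodes if kept.out_degree(n) == 0))
    net = build_network(
        edges,
        source="M9",
        sinks=sinks,
        linear_codes=TOY_LINEAR_CODES,
    )
    net.validate(pruned=True)
    return net


def default_entities() -> list[ProteinEntity]:
    """A heavy recombinant antibody and a light aggregate host-cell pool."""
    return [
        ProteinEntity(name="IgG", molecular_weight=150.0, production_rate=0.1),
        ProteinEntity(name="HCP", molecular_weight=45.0, production_rate=0.1),
    ]


#: Turnover rates (1/min), magnitudes typical of Golgi kinetic models.
_DEFAULT_KF = {
    "ManI": 887.0,
    "ManII": 1924.0,
    "GnTI": 1022.0,
    "GnTII": 1406.0,
    "GnTIV": 187.0,
    "GnTV": 1410.0,
    "b4GalT": 872.0,
    "a3SiaT": 491.0,
    "a6FucT": 291.0,
    "a3FucT": 530.0,
    "iGnT": 559.0,
}

#: Total intra-Golgi enzyme levels (uM).
_DEFAULT_ENZ = {
    "ManI": 0.29,
    "ManII": 15.0,
    "GnTI": 0.29,
    "GnTII": 1.0,
    "GnTIV": 0.04,
    "GnTV": 0.10,
    "b4GalT": 0.02,
    "a3SiaT": 0.30,
    "a6FucT": 0.09,
    "a3FucT": 0.05,
    "iGnT": 0.05,
}

#: Intra-Golgi NSD concentrations (uM), compartment-constant.
_DEFAULT_NSD = {
    "UDP-GlcNAc": 7600.0,
    "UDP-Gal": 1300.0,
    "CMP-Neu5Ac": 250.0,
    "GDP-Fuc": 460.0,
}

#: NSD dissociation constants (uM) per glycosyltransferase.
_DEFAULT_KMD = {
    "GnTI": 170.0,
    "GnTII": 170.0,
    "GnTIV": 170.0,
    "GnTV": 170.0,
    "iGnT": 170.0,
    "b4GalT": 65.0,
    "a3SiaT": 57.0,
    "a6FucT": 46.0,
    "a3FucT": 46.0,
}

#: Oligosaccharide dissociation constants (uM): high-affinity entity.
_KM_IGG = {
    "ManI": 100.0,
    "ManII": 200.0,
    "GnTI": 260.0,
    "GnTII": 190.0,
    "GnTIV": 3400.0,
    "GnTV": 3500.0,
    "b4GalT": 430.0,
    "a3SiaT": 570.0,
    "a6FucT": 25.0,
    "a3FucT": 25.0,
    "iGnT": 300.0,
}

#: Low-affinity entity: an order of magnitude or more above the heavy entity.
_KM_HCP = {
    "ManI": 6000.0,
    "ManII": 2700.0,
    "GnTI": 8600.0,
    "GnTII": 8600.0,
    "GnTIV": 8700.0,
    "GnTV": 6900.0,
    "b4GalT": 2600.0,
    "a3SiaT": 580.0,
    "a6FucT": 50.0,
    "a3FucT": 50.0,
    "iGnT": 3000.0,
}


def default_parameters(entities=None) -> KineticParameterSet:
    """The fixture ground truth theta*: plausible Golgi kinetic constants."""
    entities = entities or default_entities()
    km = {}
    for enzyme in _KM_IGG:
        for entity in entities:
            base = _KM_HCP if entity.name == "HCP" else _KM_IGG
            km[(enzyme, entity.name)] = base[enzyme]
    m9_prop = {}
    for entity in entities:
        m9_prop[entity.name] = 0.75 if entity.name == "HCP" else 0.20
    return KineticParameterSet(
        kf=dict(_DEFAULT_KF),
        enz_total=dict(_DEFAULT_ENZ),
        nsd_conc=dict(_DEFAULT_NSD),
        km=km,
        kmd=dict(_DEFAULT_KMD),
        m9_prop=m9_prop,
    )


def make_synthetic_profiles(
    net: ReactionNetwork | None = None,
    params: KineticParameterSet | None = None,
    entities=None,
    noise_sd: float = 1.0,
    seed: int = 0,
    golgi_config: GolgiConfig | None = None,
    detection_limit: float = 0.1,
) -> SyntheticProfiles:
    """Simulate the Golgi model at theta* and perturb with truncated noise.

    Tags below ``detection_limit`` percent are not reported, mimicking the
    limit of quantification of glycan analytics (a profile listing dozens of
    exact zeros would be unrealistic, and truncated noise on them would inject
    spurious mass).  Gaussian noise (sd ``noise_sd`` percent units) is added
    to each reported tag percentage, truncated at zero, and the profile
    renormalised to 100% per entity.  ``noise_sd=0`` returns the exact model
    output for the reported tags.  Raises if the model does not converge at
    theta* (fixtures must be convergent).
    """
    net = net if net is not None else make_toy_grn()
    entities = entities or default_entities()
    params = params or default_parameters(entities)
    model = assemble_golgi_model(net, entities, golgi_config=golgi_config)
    result = simulate_golgi(model, params)
    if not result.converged:
        raise RuntimeError("fixture model failed to converge at theta*")

    rng = np.random.default_rng(seed)
    rows = []
    for entity in entities:
        profile = result.profiles[entity.name]
        tags = sorted(t for t, v in profile.items() if v >= detection_limit)
        values = np.array([profile[t] for t in tags])
        if noise_sd > 0:
            values = np.clip(values + rng.normal(0.0, noise_sd, size=len(values)), 0.0, None)
        total = values.sum()
        if total <= 0:
            raise RuntimeError("noise wiped out the whole profile")
        values = 100.0 * values / total
        rows.extend(
            {"entity": entity.name, "tag": tag, "percent": float(v)}
            for tag, v in zip(tags, values)
        )
    table = pd.DataFrame(rows, columns=["entity", "tag", "percent"])
    return SyntheticProfiles(table=table, theta_star=params, result=result)
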