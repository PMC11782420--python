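"""Glycosylation reaction networks: the DAG container, I/O and sink selection.

A glycosylation reaction network (GRN) is a directed acyclic graph whose nodes
are N-glycan species (identified structurally by their LinearCode string) and
whose edges are biosynthetic reactions labelled with the catalysing
Golgi-resident enzyme.  Three on-disk dialects are supported: GraphML, a JSON
dialect and a bare edge-list CSV (``from,to,enzyme`` with LinearCode node ids).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .linearcode import parse_linear_code

__all__ = [
    "ENZYMES",
    "NetworkError",
    "StructuralError",
    "SchemaError",
    "ReactionNetwork",
    "build_network",
    "load_network",
    "save_network",
    "filter_observed_sinks",
    "tag_to_nodes",
]

#: The 11-enzyme vocabulary of Golgi-resident N-glycosylation enzymes.
ENZYMES = (
    "ManI",
    "ManII",
    "GnTI",
    "GnTII",
    "GnTIV",
    "GnTV",
    "b4GalT",
    "a3SiaT",
    "a6FucT",
    "a3FucT",
    "iGnT",
)

#: Glycosidases follow Michaelis-Menten kinetics; everything else is a
#: glycosyltransferase with sequential-order Bi-Bi kinetics.
GLYCOSIDASES = ("ManI", "ManII")


class NetworkError(Exception):
    """Base class for reaction-network errors."""


class StructuralError(NetworkError):
    """Cycle, unreachable sink or other graph-structure violation."""


class SchemaError(NetworkError):
    """Missing or malformed node/edge attributes."""


@dataclass
class ReactionNetwork:
    """Directed acyclic substrate -> product map with enzyme-labelled edges.

    Node attributes: ``linear_code`` (mandatory), ``tag``, optional
    ``observed`` flag and ``observed_abundance`` percent.  Edge attribute:
    ``enzyme`` from :data:`ENZYMES`.
    """

    graph: nx.DiGraph
    source: str
    sinks: list[str] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------------
    def nodes(self):
        return self.graph.nodes

    def edges(self):
        return self.graph.edges

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def linear_code(self, node) -> str:
        return self.graph.nodes[node]["linear_code"]

    def tag(self, node) -> str:
        return self.graph.nodes[node]["tag"]

    def enzymes(self) -> set[str]:
        """Enzymes appearing on at least one edge."""
        return {data["enzyme"] for _, _, data in self.graph.edges(data=True)}

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(self.graph.copy(), self.source, list(self.sinks))

    # -- validation ------------------------------------------------------------
    def validate(self, pruned: bool = False) -> None:
        """Check DAG-ness, attribute schema and (for pruned nets) reachability."""
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise StructuralError(f"network contains a directed cycle: {cycle}")
        for node, data in self.graph.nodes(data=True):
            if "linear_code" not in data:
                raise SchemaError(f"node {node!r} lacks a linear_code attribute")
        for u, v, data in self.graph.edges(data=True):
            enzyme = data.get("enzyme")
            if enzyme is None:
                raise SchemaError(f"edge {u!r}->{v!r} lacks an enzyme attribute")
            if enzyme not in ENZYMES:
                raise SchemaError(
                    f"edge {u!r}->{v!r} carries unknown enzyme {enzyme!r}"
                )
        if self.source not in self.graph:
            raise StructuralError(f"source node {self.source!r} not in network")
        if pruned or self.sinks:
            reachable = nx.descendants(self.graph, self.source) | {self.source}
            for sink in self.sinks:
                if sink not in self.graph:
                    raise StructuralError(f"sink {sink!r} not in network")
                if sink not in reachable:
                    raise StructuralError(
                        f"sink {sink!r} is not reachable from source {self.source!r}"
                    )


def build_network(
    edges,
    source: str,
    sinks=(),
    linear_codes: dict | None = None,
    validate: bool = True,
) -> ReactionNetwork:
    """Build a :class:`ReactionNetwork` from ``(substrate, product, enzyme)`` triples.

    ``linear_codes`` maps node id -> LinearCode; when omitted the node ids
    themselves must be LinearCode strings.  Tags are derived with the parser.
    """
    graph = nx.DiGraph()
    for u, v, enzyme in edges:
        graph.add_edge(u, v, enzyme=enzyme)
    for node in sorted(graph.nodes):
        code = (linear_codes or {}).get(node, node)
        struct = parse_linear_code(code)
        graph.nodes[node]["linear_code"] = struct.linear_code
        graph.nodes[node]["tag"] = struct.tag
    net = ReactionNetwork(graph, source, list(sinks))
    if validate:
        net.validate()
    return net


def tag_to_nodes(net: ReactionNetwork, tag: str) -> set:
    """All structural isomorphs (node ids) carrying a compositional tag.

    The LinearCode -> tag mapping is many-to-one (e.g. FA2G1 with the galactose
    on either arm), so a tag may resolve to several nodes; an absent tag yields
    an empty set.
    """
    return {n for n, data in net.graph.nodes(data=True) if data.get("tag") == tag}


def filter_observed_sinks(profiles: pd.DataFrame, threshold_percent: float = 1.0) -> list[str]:
    """Tags observed at a relative abundance strictly above the threshold.

    ``profiles`` has columns ``entity, tag, percent``; a tag is retained when
    its abundance exceeds the threshold in *any* protein entity.  Returns a
    sorted tag list; an empty result triggers a warning, not an error.
    """
    if (profiles["percent"] < 0).any():
        raise ValueError("profile abundances must be non-negative")
    keep = profiles.loc[profiles["percent"] > threshold_percent, "tag"].unique()
    tags = sorted(keep)
    if not tags:
        warnings.warn(
            f"no tag exceeds {threshold_percent}% in any entity", stacklevel=2
        )
    return tags


# -- serialization -------------------------------------------------------------

_FORMATS = ("graphml", "json", "edge-csv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".graphml":
        return "graphml"
    if suffix == ".json":
        return "json"
    if suffix == ".csv":
        return "edge-csv"
    raise ValueError(f"cannot infer network format from suffix {suffix!r}")


def save_network(net: ReactionNetwork, path, fmt: str | None = None) -> None:
    """Write a network to GraphML, the JSON dialect or an edge-list CSV."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        graph = net.graph.copy()
        graph.graph["source"] = net.source
        graph.graph["sinks"] = ";".join(net.sinks)
        nx.write_graphml(graph, path)
    elif fmt == "json":
        payload = {
            "nodes": [
                {
                    "id": n,
                    "linear_code": d["linear_code"],
                    "tag": d.get("tag"),
                    **(
                        {"observed": d["observed"]} if "observed" in d else {}
                    ),
                    **(
                        {"observed_abundance": d["observed_abundance"]}
                        if "observed_abundance" in d
                        else {}
                    ),
                }
                for n, d in sorted(net.graph.nodes(data=True))
            ],
            "edges": [
                {"from": u, "to": v, "enzyme": d["enzyme"]}
                for u, v, d in sorted(net.graph.edges(data=True))
            ],
            "source": net.source,
            "sinks": list(net.sinks),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:  # edge-csv: node ids are the LinearCode strings themselves
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["from", "to", "enzyme"])
            for u, v, d in sorted(net.graph.edges(data=True)):
                writer.writerow(
                    [net.linear_code(u), net.linear_code(v), d["enzyme"]]
                )


def load_network(path, fmt: str | None = None) -> ReactionNetwork:
    """Read a network written by :func:`save_network`; validates on load."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.DiGraph(graph)
        source = graph.graph.pop("source", None)
        sinks_raw = graph.graph.pop("sinks", "")
        sinks = [s for s in sinks_raw.split(";") if s]
        if source is None:
            source = _unique_root(graph)
        net = ReactionNetwork(graph, source, sinks)
    elif fmt == "json":
        payload = json.loads(Path(path).read_text())
        graph = nx.DiGraph()
        for node in payload["nodes"]:
            if "linear_code" not in node:
                raise SchemaError(f"JSON node {node.get('id')!r} lacks linear_code")
            attrs = {"linear_code": node["linear_code"]}
            attrs["tag"] = (
                node.get("tag") or parse_linear_code(node["linear_code"]).tag
            )
            if "observed" in node:
                attrs["observed"] = node["observed"]
            if "observed_abundance" in node:
                attrs["observed_abundance"] = node["observed_abundance"]
            graph.add_node(node["id"], **attrs)
        for edge in payload["edges"]:
            if "enzyme" not in edge:
                raise SchemaError(f"JSON edge {edge!r} lacks an enzyme")
            graph.add_edge(edge["from"], edge["to"], enzyme=edge["enzyme"])
        source = payload.get("source") or _unique_root(graph)
        net = ReactionNetwork(graph, source, list(payload.get("sinks", [])))
    else:  # edge-csv
        graph = nx.DiGraph()
        with open(path, newline="") as handle:
            reader = csv.DictReader(handle)
            for row in reader:
                graph.add_edge(row["from"], row["to"], enzyme=row["enzyme"])
        for node in sorted(graph.nodes):
            struct = parse_linear_code(node)
            graph.nodes[node]["linear_code"] = node
            graph.nodes[node]["tag"] = struct.tag
        source = _unique_root(graph)
        sinks = sorted(n for n in graph.nodes if graph.out_degree(n) == 0)
        net = ReactionNetwork(graph, source, sinks)
    net.validate(pruned=bool(net.sinks))
    return net


def _unique_root(graph: nx.DiGraph) -> str:
    roots = sorted(n for n in graph.nodes if graph.in_degree(n) == 0)
    if len(roots) != 1:
        raise StructuralError(
            f"expected a unique source (in-degree 0) node, found {roots}"
        )
    return roots[0]
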