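"""Attributed regulator networks from engagement results.

Nodes are the regulators passing the engagement cutoff; node size carries
the engagement fraction and an up/down split over engaged genes. An edge
joins two included regulators whose regulons share members, weighted by
the fraction of shared genes that are differentially expressed. Pairs
that share members but none differentially expressed are omitted from
the graph and recorded in an audit table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .config import AnalysisConfig
from .engagement import EngagementResult, RegulonSet, engaged_genes
from .expression import DeTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatorNode:
    """One included regulator: engagement fraction plus up/down split."""

    regulator: str
    size_weight: float  # engagement fraction, in [0,1]
    n_engaged: int
    frac_up: float
    frac_down: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.size_weight <= 1.0:
            raise ValueError(f"{self.regulator}: size_weight outside [0,1]")
        if self.n_engaged > 0 and abs(self.frac_up + self.frac_down - 1.0) > 1e-9:
            raise ValueError(f"{self.regulator}: frac_up + frac_down != 1")


@dataclass(frozen=True)
class RegulonEdge:
    """Shared-member link between two included regulators."""

    regulators: frozenset[str]
    n_shared: int
    n_shared_engaged: int
    width_weight: float  # n_shared_engaged / n_shared, in (0,1]

    def __post_init__(self) -> None:
        if len(self.regulators) != 2:
            raise ValueError("edge must join two distinct regulators")
        if not 0 < self.n_shared_engaged <= self.n_shared:
            raise ValueError("edge requires 0 < n_shared_engaged <= n_shared")


@dataclass
class EngagementNetwork:
    """Attributed regulator graph for one condition x timepoint."""

    condition: str
    timepoint: str
    nodes: dict[str, RegulatorNode]
    edges: list[RegulonEdge]
    config: dict = field(default_factory=dict)
    omitted_edges: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if not e.regulators <= set(self.nodes):
                raise ValueError(f"edge endpoints {set(e.regulators)} not in node set")
            if e.regulators in seen:
                raise ValueError(f"duplicate edge {set(e.regulators)}")
            seen.add(e.regulators)

    @property
    def node_names(self) -> set[str]:
        return set(self.nodes)

    def degree(self, regulator: str) -> int:
        return sum(regulator in e.regulators for e in self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(condition=self.condition, timepoint=self.timepoint)
        for n in self.nodes.values():
            g.add_node(n.regulator, size_weight=n.size_weight,
                       n_engaged=n.n_engaged, frac_up=n.frac_up,
                       frac_down=n.frac_down)
        for e in self.edges:
            a, b = sorted(e.regulators)
            g.add_edge(a, b, n_shared=e.n_shared,
                       n_shared_engaged=e.n_shared_engaged,
                       width_weight=e.width_weight)
        return g


def build_network(
    results: list[EngagementResult],
    regulons: RegulonSet,
    table: DeTable,
    config: AnalysisConfig,
) -> EngagementNetwork:
    """Assemble the regulator network from engagement results.

    ``results`` must have been computed under the same table and config;
    a result whose inclusion flag disagrees with its fraction under
    ``config`` is rejected as inconsistent.
    """
    nodes: dict[str, RegulatorNode] = {}
    for r in results:
        if r.included != (r.fraction >= config.engagement_threshold):
            raise ValueError(
                f"{r.regulator}: inclusion flag inconsistent with config threshold"
            )
        if not r.included:
            continue
        if r.n_engaged > 0:
            frac_up, frac_down = r.n_up / r.n_engaged, r.n_down / r.n_engaged
        else:
            frac_up = frac_down = 0.0
        nodes[r.regulator] = RegulatorNode(
            regulator=r.regulator, size_weight=r.fraction,
            n_engaged=r.n_engaged, frac_up=frac_up, frac_down=frac_down,
        )

    # engaged member sets for edge weights, computed once per included regulator
    engaged = {
        name: {g for g, _ in engaged_genes(regulons[name], table, config)}
        for name in nodes
        if name in regulons
    }
    edges: list[RegulonEdge] = []
    omitted = []
    names = sorted(nodes)
    for i, a in enumerate(names):
        if a not in regulons:
            continue
        for b in names[i + 1:]:
            if b not in regulons:
                continue
            shared = regulons[a].members & regulons[b].members
            if not shared:
                continue
            shared_engaged = shared & (engaged[a] | engaged[b])
            if shared_engaged:
                edges.append(
                    RegulonEdge(
                        regulators=frozenset((a, b)),
                        n_shared=len(shared),
                        n_shared_engaged=len(shared_engaged),
                        width_weight=len(shared_engaged) / len(shared),
                    )
                )
            else:
                omitted.append((a, b, len(shared)))
    omitted_df = pd.DataFrame(omitted, columns=["regulator_a", "regulator_b", "n_shared"])
    return EngagementNetwork(
        condition=table.condition, timepoint=table.timepoint,
        nodes=nodes, edges=edges, config=config.to_dict(),
        omitted_edges=omitted_df,
    )


def classify_independence(net: EngagementNetwork) -> tuple[set[str], set[str]]:
    """Split nodes into (networked, network-independent) by degree.

    A network-independent regulator passes the engagement cutoff but
    shares no differentially expressed regulon members with any other
    included regulator (degree 0).
    """
    touched: set[str] = set()
    for e in net.edges:
        touched |= e.regulators
    independent = net.node_names - touched
    return touched, independent


def network_to_dict(net: EngagementNetwork) -> dict:
    return {
        "condition": net.condition,
        "timepoint": net.timepoint,
        "config": net.config,
        "nodes": [
            {"regulator": n.regulator, "size_weight": n.size_weight,
             "n_engaged": n.n_engaged, "frac_up": n.frac_up,
             "frac_down": n.frac_down}
            for n in (net.nodes[k] for k in sorted(net.nodes))
        ],
        "edges": [
            {"regulators": sorted(e.regulators), "n_shared": e.n_shared,
             "n_shared_engaged": e.n_shared_engaged,
             "width_weight": e.width_weight}
            for e in sorted(net.edges, key=lambda e: sorted(e.regulators))
        ],
    }


def network_from_dict(d: dict) -> EngagementNetwork:
    nodes = {
        n["regulator"]: RegulatorNode(
            regulator=n["regulator"], size_weight=n["size_weight"],
            n_engaged=n["n_engaged"], frac_up=n["frac_up"],
            frac_down=n["frac_down"],
        )
        for n in d["nodes"]
    }
    edges = [
        RegulonEdge(
            regulators=frozenset(e["regulators"]), n_shared=e["n_shared"],
            n_shared_engaged=e["n_shared_engaged"],
            width_weight=e["width_weight"],
        )
        for e in d["edges"]
    ]
    return EngagementNetwork(
        condition=d["condition"], timepoint=d["timepoint"],
        nodes=nodes, edges=edges, config=d.get("config", {}),
    )


def export_network(net: EngagementNetwork, path: str | Path, format: str) -> None:
    """Write the network as GraphML (attributed), SIF (topology) or JSON."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "graphml":
        nx.write_graphml(net.to_networkx(), path)
    elif fmt == "sif":
        lines = [
            f"{a}\tshares\t{b}"
            for a, b in (sorted(e.regulators) for e in
                         sorted(net.edges, key=lambda e: sorted(e.regulators)))
        ]
        isolated = sorted(net.node_names - {r for e in net.edges for r in e.regulators})
        lines += isolated  # SIF convention: bare node name for isolates
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "json":
        path.write_text(json.dumps(network_to_dict(net), indent=2) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_json(path: str | Path) -> EngagementNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))


def export_attribute_tables(net: EngagementNetwork, prefix: str | Path) -> None:
    """Write node and edge attribute TSVs next to ``prefix``."""
    prefix = Path(prefix)
    nodes = pd.DataFrame(
        [(n.regulator, n.size_weight, n.n_engaged, n.frac_up, n.frac_down)
         for n in (net.nodes[k] for k in sorted(net.nodes))],
        columns=["regulator", "size_weight", "n_engaged", "frac_up", "frac_down"],
    )
    nodes.to_csv(f"{prefix}.nodes.tsv", sep="\t", index=False)
    edges = pd.DataFrame(
        [(*sorted(e.regulators), e.n_shared, e.n_shared_engaged, e.width_weight)
         for e in sorted(net.edges, key=lambda e: sorted(e.regulators))],
        columns=["regulator_a", "regulator_b", "n_shared", "n_shared_engaged",
                 "width_weight"],
    )
    edges.to_csv(f"{prefix}.edges.tsv", sep="\t", index=False)
    if net.omitted_edges is not None:
        net.omitted_edges.to_csv(f"{prefix}.omitted_edges.tsv", sep="\t", index=False)
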