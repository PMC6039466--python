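"""Merging condition networks and isolating the linking region.

When several condition-specific hub subnetworks are merged, each node
carries a provenance set — the conditions whose network contains it.
The merged node set then partitions into condition-specific classes
(provenance of size one) and the *linking* class (provenance of two or
more conditions), the common axis of the conditions. An alternative
"bridge" rule, which additionally promotes specific nodes adjacent to
two or more conditions, is available behind a flag but is not the
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import networkx as nx
import pandas as pd

from .hubs import HubSubnetwork

__all__ = [
    "MergedNetwork",
    "merge_networks",
    "linking_subnetwork",
    "provenance_report",
    "LINKING_LABEL",
]

log = logging.getLogger(__name__)

LINKING_LABEL = "linking"

NetworkLike = Union[nx.Graph, HubSubnetwork]


@dataclass
class MergedNetwork:
    """Union of condition networks with per-node provenance.

    ``partition`` maps every node to either ``"linking"`` or
    ``"specific:<condition>"``.
    """

    graph: nx.Graph
    provenance: dict[str, frozenset[str]]
    partition: dict[str, str]
    conditions: tuple[str, ...]

    @property
    def linking_nodes(self) -> frozenset[str]:
        return frozenset(
            n for n, p in self.partition.items() if p == LINKING_LABEL
        )

    def specific_nodes(self, condition: str) -> frozenset[str]:
        label = f"specific:{condition}"
        return frozenset(
            n for n, p in self.partition.items() if p == label
        )


def _as_graph(net: NetworkLike) -> nx.Graph:
    return net.graph if isinstance(net, HubSubnetwork) else net


def merge_networks(
    nets: Sequence[tuple[str, NetworkLike]],
    linking_rule: str = "membership",
) -> MergedNetwork:
    """Merge labelled condition networks into one provenance-annotated graph.

    ``nets`` is a sequence of ``(condition, network)`` pairs with
    distinct condition labels. The merged graph is the node-wise and
    edge-wise union. Under the default ``membership`` rule a node is
    linking iff it belongs to >= 2 condition networks; the ``bridge``
    rule additionally marks single-condition nodes whose merged-graph
    neighbors span >= 2 conditions.
    """
    if len(nets) < 2:
        raise ValueError("need at least 2 networks to merge")
    labels = [c for c, _ in nets]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    if linking_rule not in ("membership", "bridge"):
        raise ValueError(f"unknown linking rule: {linking_rule!r}")

    merged = nx.Graph(name="merged")
    provenance: dict[str, set[str]] = {}
    for condition, net in nets:
        g = _as_graph(net)
        for n in g.nodes():
            provenance.setdefault(n, set()).add(condition)
        merged.add_nodes_from(g.nodes())
        merged.add_edges_from(g.edges())

    partition: dict[str, str] = {}
    for n, prov in provenance.items():
        if len(prov) >= 2:
            partition[n] = LINKING_LABEL
        else:
            partition[n] = f"specific:{next(iter(prov))}"
    if linking_rule == "bridge":
        for n, label in list(partition.items()):
            if label == LINKING_LABEL:
                continue
            neighbor_conditions: set[str] = set()
            for m in merged.neighbors(n):
                neighbor_conditions |= provenance[m]
            if len(neighbor_conditions) >= 2:
                partition[n] = LINKING_LABEL

    if not any(p == LINKING_LABEL for p in partition.values()):
        log.warning("merged networks share no nodes: linking set is empty")
    return MergedNetwork(
        graph=merged,
        provenance={n: frozenset(p) for n, p in provenance.items()},
        partition=partition,
        conditions=tuple(sorted(labels)),
    )


def linking_subnetwork(m: MergedNetwork) -> nx.Graph:
    """Induced subgraph of the merged graph on the linking nodes.

    The result feeds straight back into ``topology.global_stats`` and
    ``hubs.select_hubs`` to produce the linking-region hubs. Edges
    between a specific and a linking node stay in the merged graph but
    not here (induced-subgraph consistency). Raises ``ValueError``
    when the linking set is empty.
    """
    linking = m.linking_nodes
    if not linking:
        raise ValueError("no linking region: merged networks share no nodes")
    sub = m.graph.subgraph(linking).copy()
    sub.name = "linking"
    return sub


def provenance_report(m: MergedNetwork) -> dict:
    """Partition counts and the pairwise provenance-overlap matrix.

    Returns a dict with ``specific_counts`` (condition -> node count),
    ``linking_count``, ``total_nodes``, ``total_edges`` and
    ``overlap`` — a condition×condition DataFrame whose (i, j) entry
    is the number of merged nodes belonging to both condition networks
    (diagonal = per-condition network sizes).
    """
    conditions = list(m.conditions)
    specific = {
        c: len(m.specific_nodes(c)) for c in conditions
    }
    linking_count = len(m.linking_nodes)
    overlap = pd.DataFrame(0, index=conditions, columns=conditions, dtype=int)
    for prov in m.provenance.values():
        for a in prov:
            for b in prov:
                overlap.loc[a, b] += 1
    return {
        "specific_counts": specific,
        "linking_count": linking_count,
        "total_nodes": m.graph.number_of_nodes(),
        "total_edges": m.graph.number_of_edges(),
        "overlap": overlap,
    }
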