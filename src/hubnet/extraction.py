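"""First-order interaction network extraction.

A condition's network is grown from its seed proteins by mapping them
onto the interactome and keeping the seeds plus all of their direct
interaction partners, with every interactome edge between retained
nodes (the induced subgraph). This is the standard "first order
interaction network" construction and explains why a hundred seeds can
expand into a network of thousands of nodes on a dense interactome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .io import SeedSet

__all__ = ["FirstOrderNetwork", "extract_first_order", "largest_component"]

log = logging.getLogger(__name__)


@dataclass
class FirstOrderNetwork:
    """A seed-grown network together with seed-mapping provenance.

    seeds_found
        Seeds present in the extracted graph.
    seeds_missing
        Seeds absent from the interactome altogether.
    seeds_isolated
        Seeds present in the interactome but without any interaction
        partner; they are kept in the graph only when extraction was run
        with ``keep_isolated_seeds`` (isolated nodes distort path
        statistics, so the default drops them).
    """

    graph: nx.Graph
    seeds_found: frozenset[str]
    seeds_missing: frozenset[str]
    condition: str
    seeds_isolated: frozenset[str] = field(default_factory=frozenset)


def extract_first_order(
    interactome: nx.Graph,
    seeds: SeedSet,
    keep_isolated_seeds: bool = False,
) -> FirstOrderNetwork:
    """Extract the first-order interaction network of a seed set.

    The node set is (seeds ∩ interactome) ∪ neighbors(seeds) and the
    edge set is every interactome edge with both endpoints retained
    (induced subgraph). Raises ``ValueError`` when no seed maps onto
    the interactome.
    """
    if interactome.number_of_nodes() == 0:
        raise ValueError("interactome is empty")
    in_graph = frozenset(s for s in seeds.members if s in interactome)
    missing = frozenset(seeds.members) - in_graph
    if not in_graph:
        raise ValueError(
            f"no seed of condition {seeds.condition!r} maps to the interactome"
        )
    if missing:
        log.warning(
            "%d/%d seeds of %s not found in the interactome",
            len(missing), len(seeds.members), seeds.condition,
        )
    nodes: set[str] = set(in_graph)
    for s in in_graph:
        nodes.update(interactome.neighbors(s))
    sub = interactome.subgraph(nodes).copy()
    sub.name = f"{seeds.condition}_first_order"

    isolated = frozenset(s for s in in_graph if interactome.degree(s) == 0)
    found = in_graph
    if isolated and not keep_isolated_seeds:
        sub.remove_nodes_from(isolated)
        found = in_graph - isolated
        log.warning(
            "%d isolated seed(s) dropped from %s", len(isolated), seeds.condition
        )
    return FirstOrderNetwork(
        graph=sub,
        seeds_found=found,
        seeds_missing=missing,
        condition=seeds.condition,
        seeds_isolated=isolated,
    )


def largest_component(g: nx.Graph) -> nx.Graph:
    """Return the connected component with the most nodes.

    Ties break deterministically toward the component containing the
    lexicographically smallest node symbol.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    components = sorted(
        nx.connected_components(g), key=lambda c: (-len(c), min(c))
    )
    out = g.subgraph(components[0]).copy()
    out.name = g.name
    return out
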