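"""HUB node selection and hub-connecting subnetwork extraction.

A HUB is a node with exceptionally high centrality, interpreted as a
coordination point of the network. Three auditable selection
strategies are shipped, with the degree+betweenness Borda rank as
default; the strategy and its parameters travel with every result so
downstream artifacts are reproducible.

The subnetwork "connecting" the hubs likewise admits several readings;
three are provided, with the union of all hub–hub geodesics (every
tied shortest path kept, no sampling) as the deterministic default.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "HubResult",
    "HubSubnetwork",
    "select_hubs",
    "extract_hub_subnetwork",
    "HUB_STRATEGIES",
    "SUBNETWORK_STRATEGIES",
]

log = logging.getLogger(__name__)

HUB_STRATEGIES = ("degree_betweenness_borda", "degree_topk", "sd_threshold")
SUBNETWORK_STRATEGIES = ("induced", "neighbors", "geodesic_union")


@dataclass
class HubResult:
    """Selected hubs plus the full ranking they were taken from."""

    hubs: list[str]
    strategy: str
    parameters: dict
    ranking: pd.DataFrame


@dataclass
class HubSubnetwork:
    """The network connecting a set of hubs, with strategy provenance."""

    graph: nx.Graph
    hubs: list[str]
    strategy: str


def _ordered_ranking(ct: pd.DataFrame, sort_cols: list, ascending: list) -> pd.DataFrame:
    ranking = ct.copy()
    ranking["_symbol"] = ranking.index
    ranking = ranking.sort_values(sort_cols + ["_symbol"],
                                  ascending=ascending + [True])
    return ranking.drop(columns="_symbol")


def select_hubs(
    ct: pd.DataFrame,
    n_hubs: int = 8,
    strategy: str = "degree_betweenness_borda",
    k_sd: float = 2.0,
) -> HubResult:
    """Select HUB nodes from a centrality table.

    Strategies
    ----------
    degree_betweenness_borda (default)
        Rank every node by degree and by betweenness (competition
        ranks, best = 1); the Borda score is the sum of the two ranks
        and the ``n_hubs`` lowest scores win.
    degree_topk
        The ``n_hubs`` highest-degree nodes.
    sd_threshold
        Every node whose degree exceeds mean + ``k_sd``·sd (population
        sd); may select no nodes on near-regular networks, which is
        allowed and logged.

    All ties break by higher betweenness, then lexicographic symbol.
    """
    if strategy not in HUB_STRATEGIES:
        raise ValueError(f"unknown hub strategy: {strategy!r}")
    for col in ("degree", "betweenness"):  # betweenness breaks all ties
        if col not in ct.columns:
            raise ValueError(f"centrality table lacks a {col!r} column")
    n = len(ct)
    params: dict = {"n_hubs": n_hubs}

    if strategy == "sd_threshold":
        params = {"k_sd": k_sd}
        mean = ct["degree"].mean()
        sd = ct["degree"].std(ddof=0)
        threshold = mean + k_sd * sd
        ranking = _ordered_ranking(
            ct, ["degree", "betweenness"], [False, False]
        )
        ranking["borda_score"] = pd.NA
        hubs = [v for v in ranking.index if ct.loc[v, "degree"] > threshold]
        if not hubs:
            log.warning(
                "sd_threshold(k_sd=%.3g) selected no hubs "
                "(degree threshold %.3g)", k_sd, threshold
            )
        params["threshold"] = float(threshold)
        return HubResult(hubs=hubs, strategy=strategy,
                         parameters=params, ranking=ranking)

    if n_hubs < 1:
        raise ValueError("n_hubs must be >= 1")
    if n_hubs > n:
        raise ValueError(f"n_hubs={n_hubs} exceeds the {n} available nodes")

    if strategy == "degree_topk":
        ranking = _ordered_ranking(
            ct, ["degree", "betweenness"], [False, False]
        )
        ranking["borda_score"] = pd.NA
    else:  # degree_betweenness_borda
        r_deg = ct["degree"].rank(ascending=False, method="min")
        r_bet = ct["betweenness"].rank(ascending=False, method="min")
        ranking = ct.copy()
        ranking["borda_score"] = r_deg + r_bet
        ranking = _ordered_ranking(
            ranking, ["borda_score", "betweenness"], [True, False]
        )
    hubs = list(ranking.index[:n_hubs])
    return HubResult(hubs=hubs, strategy=strategy,
                     parameters=params, ranking=ranking)


def _geodesic_union(g: nx.Graph, hubs: Sequence[str]) -> nx.Graph:
    """Union of every shortest path between every hub pair.

    For each source hub a BFS builds the shortest-path predecessor DAG;
    for every other hub reachable from it, walking the DAG backwards
    collects exactly the nodes and edges lying on some tied geodesic.
    Unreachable hub pairs contribute nothing.
    """
    out = nx.Graph()
    out.add_nodes_from(hubs)
    hubset = list(dict.fromkeys(hubs))
    for i, s in enumerate(hubset):
        dist = {s: 0}
        preds: dict = {}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for w in g.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    preds[w] = [v]
                    queue.append(w)
                elif dist[w] == dist[v] + 1:
                    preds[w].append(v)
        for t in hubset[i + 1:]:
            if t not in dist:
                log.warning("hubs %s and %s are disconnected", s, t)
                continue
            seen = {t}
            stack = [t]
            while stack:
                w = stack.pop()
                for p in preds.get(w, ()):
                    out.add_edge(p, w)
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
    return out


def extract_hub_subnetwork(
    g: nx.Graph,
    hubs: Iterable[str],
    strategy: str = "geodesic_union",
) -> HubSubnetwork:
    """Extract the subnetwork connecting the given hubs.

    ``induced``: the induced subgraph on the hubs alone.
    ``neighbors``: the induced subgraph on hubs plus their first
    neighbors.
    ``geodesic_union`` (default): hubs plus every interior node and
    edge of every shortest path between every hub pair, all ties kept.
    """
    hubs = list(dict.fromkeys(hubs))
    if strategy not in SUBNETWORK_STRATEGIES:
        raise ValueError(f"unknown subnetwork strategy: {strategy!r}")
    for h in hubs:
        if h not in g:
            raise ValueError(f"hub {h!r} is not a node of the network")
    if strategy == "induced":
        sub = g.subgraph(hubs).copy()
    elif strategy == "neighbors":
        nodes = set(hubs)
        for h in hubs:
            nodes.update(g.neighbors(h))
        sub = g.subgraph(nodes).copy()
    else:
        if len(hubs) < 2:
            raise ValueError("geodesic_union requires at least 2 hubs")
        sub = _geodesic_union(g, hubs)
    sub.name = f"{g.name}_hub_{strategy}" if g.name else f"hub_{strategy}"
    return HubSubnetwork(graph=sub, hubs=hubs, strategy=strategy)
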