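"""Global topology panel and per-node centralities.

Conventions follow Cytoscape's NetworkAnalyzer, the de-facto standard
for descriptive PPI network statistics:

* degree centralization  = (N/(N-2)) * (max_degree/(N-1) - density)
* network heterogeneity  = coefficient of variation of degree
  (population variance), a hub-dominance index
* clustering coefficient = mean of local coefficients, with degree<2
  nodes contributing 0
* characteristic path length (CPL) = mean shortest-path distance over
  connected node pairs only; the fraction of connected pairs is
  reported alongside
* betweenness is normalized by (N-1)(N-2)/2, closeness is computed
  within each connected component as (reachable)/(sum of distances),
  and stress is the raw count of geodesics crossing a node as an
  interior vertex
* the degree distribution is fitted by least squares on log n(k) vs
  log k for k >= 1 (NetworkAnalyzer-style), not by MLE

Betweenness and CPL are delegated to igraph's C implementations for
speed on multi-thousand-node networks; stress and closeness use a
hand-written BFS accumulation over the shortest-path DAG, since no
installed library exposes stress centrality.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TopologyReport",
    "PowerLawFit",
    "global_stats",
    "node_centralities",
    "degree_distribution",
    "fit_power_law",
    "ALL_MEASURES",
]

ALL_MEASURES = ("degree", "betweenness", "closeness", "stress", "clustering")


@dataclass(frozen=True)
class TopologyReport:
    """Global topology panel of a network.

    ``centralization`` is ``None`` (undefined) for networks with fewer
    than three nodes. ``characteristic_path_length`` is NaN for
    edgeless networks.
    """

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    centralization: float | None
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float
    connected_pair_fraction: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log least-squares fit of a degree distribution.

    ``exponent`` is the slope of log n(k) vs log k (negative for
    decreasing, heavy-tailed distributions); ``support`` lists the
    degrees used.
    """

    exponent: float
    r_squared: float
    support: tuple[int, ...]


def _to_igraph(g: nx.Graph) -> tuple[ig.Graph, list]:
    """Convert to igraph over sorted nodes; returns (graph, node order)."""
    nodes = sorted(g.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in g.edges()]
    return ig.Graph(n=len(nodes), edges=edges, directed=False), nodes


def node_centralities(
    g: nx.Graph, measures: Iterable[str] = ALL_MEASURES
) -> pd.DataFrame:
    """Per-node centrality table, indexed by node symbol (sorted).

    Columns are drawn from ``degree``, ``betweenness`` (normalized to
    [0, 1]), ``closeness`` (per-component, [0, 1]), ``stress``
    (unnormalized geodesic count) and ``clustering``.
    """
    measures = tuple(measures)
    unknown = set(measures) - set(ALL_MEASURES)
    if unknown:
        raise ValueError(f"unknown centrality measures: {sorted(unknown)}")
    nodes = sorted(g.nodes())
    n = len(nodes)
    table: dict[str, object] = {}
    if "degree" in measures:
        table["degree"] = [g.degree(v) for v in nodes]
    if "betweenness" in measures:
        igg, _ = _to_igraph(g)
        raw = igg.betweenness(directed=False)
        norm = (n - 1) * (n - 2) / 2.0
        table["betweenness"] = (
            [b / norm for b in raw] if norm > 0 else [0.0] * n
        )
    if "closeness" in measures or "stress" in measures:
        closeness, stress = _closeness_and_stress(
            g, nodes, want_stress="stress" in measures
        )
        if "closeness" in measures:
            table["closeness"] = [closeness[v] for v in nodes]
        if "stress" in measures:
            table["stress"] = [stress[v] for v in nodes]
    if "clustering" in measures:
        cc = nx.clustering(g)
        table["clustering"] = [cc[v] for v in nodes]
    df = pd.DataFrame(table, index=pd.Index(nodes, name="node"))
    return df[[m for m in measures]]


def _closeness_and_stress(
    g: nx.Graph, nodes: Sequence, want_stress: bool
) -> tuple[dict, dict]:
    adj = {n: list(g.neighbors(n)) for n in nodes}
    closeness = {n: 0.0 for n in nodes}
    acc = {n: 0 for n in nodes}
    for s in nodes:
        dist = {s: 0}
        sigma = {s: 1}
        preds: dict = {}
        order = [s]
        queue = deque([s])
        while queue:
            v = queue.popleft()
            dv = dist[v]
            sv = sigma[v]
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dv + 1
                    sigma[w] = sv
                    preds[w] = [v]
                    order.append(w)
                    queue.append(w)
                elif dist[w] == dv + 1:
                    sigma[w] += sv
                    preds[w].append(v)
        total = sum(dist.values())
        if total > 0:
            closeness[s] = (len(dist) - 1) / total
        if want_stress:
            # suffixes[v] = number of geodesic continuations from v to
            # any strictly farther target in the s-rooted DAG
            suffixes = {v: 0 for v in order}
            for w in reversed(order):
                if w == s:
                    continue
                inc = 1 + suffixes[w]
                for p in preds[w]:
                    suffixes[p] += inc
            for v in order:
                if v != s:
                    acc[v] += sigma[v] * suffixes[v]
    # each unordered (s, t) pair was counted from both endpoints
    stress = {n: acc[n] // 2 for n in nodes}
    return closeness, stress


def global_stats(g: nx.Graph, giant_only: bool = False) -> TopologyReport:
    """Compute the global topology panel of a network.

    With ``giant_only`` the statistics are computed on the largest
    connected component (lexicographic tie-break), which matters for
    path-length comparability across networks.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if giant_only:
        from .extraction import largest_component

        g = largest_component(g)
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = nx.density(g) if n > 1 else 0.0
    avg_neighbors = 2.0 * e / n
    mean_deg = degrees.mean()
    heterogeneity = (
        float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else 0.0
    )
    if n < 3:
        centralization: float | None = None
    else:
        centralization = (n / (n - 2.0)) * (degrees.max() / (n - 1.0) - density)
    clustering = (
        float(np.mean(list(nx.clustering(g).values()))) if n > 0 else 0.0
    )
    comp_sizes = [len(c) for c in nx.connected_components(g)]
    connected_pairs = sum(s * (s - 1) for s in comp_sizes)
    pair_fraction = connected_pairs / (n * (n - 1)) if n > 1 else 0.0
    if e == 0:
        cpl = float("nan")
    else:
        igg, _ = _to_igraph(g)
        cpl = float(igg.average_path_length(directed=False, unconn=True))
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=clustering,
        centralization=centralization,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        density=float(density),
        heterogeneity=heterogeneity,
        connected_pair_fraction=float(pair_fraction),
    )


def degree_distribution(g: nx.Graph) -> pd.DataFrame:
    """Degree frequency table: columns ``degree``, ``count``; ascending
    degree; only degrees with nonzero frequency appear."""
    counts: dict[int, int] = {}
    for _, d in g.degree():
        counts[d] = counts.get(d, 0) + 1
    rows = sorted(counts.items())
    return pd.DataFrame(rows, columns=["degree", "count"])


def fit_power_law(dist: pd.DataFrame) -> PowerLawFit:
    """Least-squares line through (log k, log n(k)) for degrees k >= 1.

    Raises ``ValueError`` with "insufficient support" when fewer than
    three distinct positive degrees are present.
    """
    sub = dist[dist["degree"] >= 1]
    if len(sub) < 3:
        raise ValueError(
            f"insufficient support for power-law fit: "
            f"{len(sub)} positive-degree point(s), need >= 3"
        )
    x = np.log10(sub["degree"].to_numpy(dtype=float))
    y = np.log10(sub["count"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = min(1.0, max(0.0, r2))
    return PowerLawFit(
        exponent=float(slope),
        r_squared=r2,
        support=tuple(int(k) for k in sub["degree"]),
    )
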