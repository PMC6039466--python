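"""Brute-force centrality oracle: explicit enumeration of all geodesics.

Independent of the package's BFS/igraph implementations — every
shortest path between every pair is materialized with
``networkx.all_shortest_paths`` and interior memberships are counted
directly.
"""

from itertools import combinations

import networkx as nx


def brute_force_centralities(g: nx.Graph):
    """Return (betweenness, closeness, stress) dicts by enumeration."""
    nodes = sorted(g.nodes())
    n = len(nodes)
    betweenness = {v: 0.0 for v in nodes}
    stress = {v: 0 for v in nodes}
    for s, t in combinations(nodes, 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for v in nodes:
            if v == s or v == t:
                continue
            crossing = sum(1 for p in paths if v in p)
            stress[v] += crossing
            betweenness[v] += crossing / len(paths)
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        betweenness = {v: b / norm for v, b in betweenness.items()}
    closeness = {}
    for v in nodes:
        dist = nx.single_source_shortest_path_length(g, v)
        total = sum(dist.values())
        closeness[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return betweenness, closeness, stress


def brute_force_cpl(g: nx.Graph) -> float:
    """Mean shortest-path length over connected unordered pairs."""
    dists = []
    for s, t in combinations(sorted(g.nodes()), 2):
        if nx.has_path(g, s, t):
            dists.append(nx.shortest_path_length(g, s, t))
    return sum(dists) / len(dists)
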