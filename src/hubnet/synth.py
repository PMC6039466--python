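"""Synthetic inputs with planted ground truth.

Generates everything the pipeline consumes — a scale-free interactome,
overlapping condition seed lists, and a miRNA→target map — from a
single seed, so every stage is testable end-to-end without any
database download. The interactome is a preferential-attachment
("rich get richer") graph, matching the only distributional property
the real interactomes are claimed to have: a heavy-tailed, power-law
degree distribution. Planted structure (boosted-degree hubs, a shared
seed core) provides the ground truth that recovery tests check
against.

All randomness flows through one ``numpy.random.Generator`` per call;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .io import MiRNATargetMap, SeedSet

__all__ = [
    "SyntheticTruth",
    "generate_interactome",
    "plant_hubs",
    "generate_condition_seeds",
    "generate_mirna_targets",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of a synthetic instance."""

    planted_hubs: dict
    planted_linking: frozenset[str]
    generator_params: dict

    def to_dict(self) -> dict:
        return {
            "planted_hubs": {
                c: sorted(hs) for c, hs in self.planted_hubs.items()
            },
            "planted_linking": sorted(self.planted_linking),
            "generator_params": dict(self.generator_params),
        }


def _node_label(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_interactome(
    n_nodes: int, attachment_m: int, random_seed: int
) -> nx.Graph:
    """Preferential-attachment interactome with gene-like node labels.

    Starts from a star on ``attachment_m + 1`` nodes and attaches each
    new node with ``attachment_m`` edges preferentially to high-degree
    nodes, giving a connected simple graph with exactly
    ``attachment_m * (n_nodes - attachment_m)`` edges and a
    heavy-tailed degree distribution.
    """
    if attachment_m < 1:
        raise ValueError("attachment_m must be >= 1")
    if n_nodes <= attachment_m:
        raise ValueError("n_nodes must exceed attachment_m")
    g = nx.barabasi_albert_graph(n_nodes, attachment_m, seed=int(random_seed))
    width = max(4, len(str(n_nodes - 1)))
    g = nx.relabel_nodes(g, {i: _node_label(i, width) for i in g.nodes()})
    g.name = f"synthetic_interactome_n{n_nodes}_m{attachment_m}"
    return g


def plant_hubs(
    g: nx.Graph,
    n_hubs: int,
    boost_factor: float = 5.0,
    random_seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Plant dominant hubs by boosting the degree of random nodes.

    Each planted node receives random new edges until its degree
    reaches ``boost_factor`` times the maximum pre-planting degree
    (capped at n-1, a maximally connected hub), so planted hubs
    dominate every natural hub the way disease hubs dominate a
    first-order disease network. Returns a boosted copy and the
    planted node list (sorted).
    """
    if n_hubs < 1 or n_hubs > g.number_of_nodes():
        raise ValueError("n_hubs out of range")
    rng = np.random.default_rng(random_seed)
    nodes = sorted(g.nodes())
    max_deg = max(d for _, d in g.degree())
    target = min(math.ceil(boost_factor * max_deg), g.number_of_nodes() - 1)
    planted = sorted(
        rng.choice(np.array(nodes, dtype=object), size=n_hubs, replace=False)
    )
    boosted = g.copy()
    for hub in planted:
        candidates = np.array(
            [n for n in nodes if n != hub and not boosted.has_edge(hub, n)],
            dtype=object,
        )
        need = min(target - boosted.degree(hub), len(candidates))
        if need > 0:
            partners = rng.choice(candidates, size=need, replace=False)
            boosted.add_edges_from((hub, p) for p in partners)
    return boosted, [str(p) for p in planted]


def generate_condition_seeds(
    g: nx.Graph,
    n_conditions: int,
    seeds_per_condition: int,
    overlap_fraction: float,
    hub_bias: bool = True,
    random_seed: int = 0,
    must_include: Sequence[str] = (),
    labels: Sequence[str] | None = None,
) -> tuple[list[SeedSet], SyntheticTruth]:
    """Overlapping condition seed sets with a shared planted core.

    A core of ``round(overlap_fraction * seeds_per_condition)`` genes
    — sampled degree-proportionally when ``hub_bias`` — is included in
    every condition; the remaining seeds of each condition are sampled
    disjointly from the rest of the node universe. ``must_include``
    genes (e.g. planted hubs) are forced into the core. The truth
    records the core as the planted linking ancestry.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    nodes = sorted(g.nodes())
    n = len(nodes)
    if seeds_per_condition > n:
        raise ValueError("seeds_per_condition exceeds the node universe")
    if labels is None:
        labels = [f"cond{i + 1}" for i in range(n_conditions)]
    if len(labels) != n_conditions or len(set(labels)) != n_conditions:
        raise ValueError("labels must be distinct and match n_conditions")

    rng = np.random.default_rng(random_seed)
    n_core = round(overlap_fraction * seeds_per_condition)
    core: list[str] = []
    for m in must_include:
        if m not in g:
            raise ValueError(f"must_include gene {m!r} not in the graph")
        if m not in core:
            core.append(m)
    n_core = max(n_core, len(core))
    n_specific = seeds_per_condition - n_core
    if n_core + n_conditions * n_specific > n:
        raise ValueError(
            "infeasible sizes: disjoint specific seeds exceed the universe"
        )

    pool = np.array([v for v in nodes if v not in set(core)], dtype=object)
    if len(core) < n_core:
        if hub_bias:
            deg = np.array([g.degree(v) for v in pool], dtype=float)
            p = deg / deg.sum() if deg.sum() > 0 else None
        else:
            p = None
        extra = rng.choice(pool, size=n_core - len(core), replace=False, p=p)
        core.extend(str(v) for v in extra)
    core_set = frozenset(core)

    remaining = np.array([v for v in nodes if v not in core_set], dtype=object)
    seed_sets: list[SeedSet] = []
    for label in labels:
        if n_specific > 0:
            picked = rng.choice(remaining, size=n_specific, replace=False)
            picked_set = {str(v) for v in picked}
            remaining = np.array(
                [v for v in remaining if v not in picked_set], dtype=object
            )
        else:
            picked_set = set()
        seed_sets.append(
            SeedSet(condition=label, members=frozenset(core_set | picked_set))
        )
    truth = SyntheticTruth(
        planted_hubs={label: tuple(must_include) for label in labels},
        planted_linking=core_set,
        generator_params={
            "n_nodes": n,
            "n_conditions": n_conditions,
            "seeds_per_condition": seeds_per_condition,
            "overlap_fraction": overlap_fraction,
            "hub_bias": hub_bias,
            "random_seed": int(random_seed),
        },
    )
    return seed_sets, truth


def generate_mirna_targets(
    g: nx.Graph,
    mirna_count: int,
    targets_per_mirna_mean: float = 5.0,
    hub_enrichment: float = 0.0,
    random_seed: int = 0,
) -> MiRNATargetMap:
    """Synthetic miRNA→target map over the graph's gene universe.

    Each miRNA draws a positive target count from a Poisson
    distribution truncated at >= 1; with ``hub_enrichment`` in (0, 1],
    that fraction of its targets is drawn degree-proportionally (so
    some miRNAs target multiple hubs), the rest uniformly.
    """
    if mirna_count < 1:
        raise ValueError("mirna_count must be >= 1")
    if not 0.0 <= hub_enrichment <= 1.0:
        raise ValueError("hub_enrichment must be in [0, 1]")
    rng = np.random.default_rng(random_seed)
    nodes = np.array(sorted(g.nodes()), dtype=object)
    deg = np.array([g.degree(v) for v in nodes], dtype=float)
    p_deg = deg / deg.sum() if deg.sum() > 0 else None
    width = max(4, len(str(mirna_count)))
    mapping: dict[str, frozenset[str]] = {}
    for i in range(mirna_count):
        k = int(rng.poisson(targets_per_mirna_mean))
        while k == 0:
            k = int(rng.poisson(targets_per_mirna_mean))
        k = min(k, len(nodes))
        k_hub = round(hub_enrichment * k) if p_deg is not None else 0
        targets: set[str] = set()
        if k_hub > 0:
            targets |= {
                str(v)
                for v in rng.choice(nodes, size=k_hub, replace=False, p=p_deg)
            }
        rest = np.array([v for v in nodes if v not in targets], dtype=object)
        k_uni = min(k - len(targets), len(rest))
        if k_uni > 0:
            targets |= {
                str(v) for v in rng.choice(rest, size=k_uni, replace=False)
            }
        mapping[f"syn-mir-{i + 1:0{width}d}"] = frozenset(targets)
    return MiRNATargetMap(mapping=mapping)
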