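"""miRNA overlay networks and hub-targeting summaries.

The overlay is a strictly bipartite graph connecting miRNAs to the
genes of a node set of interest (typically the linking region of a
merged network, or its hubs). A reference miRNA→hub map for the seven
hubs linking the bladder/kidney/prostate arsenical networks (RXRA,
MAP3K7, NR3C1, PABPC1, NDRG1, RELA, CTNNB1) ships with the package
and doubles as a self-contained worked example: 73 distinct miRNAs,
10 of which target two or three hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .io import MiRNATargetMap, normalize_symbol, read_mirna_targets

__all__ = [
    "OverlayNetwork",
    "HubTargetSummary",
    "build_overlay",
    "summarize_hub_targeting",
    "load_reference_hub_targets",
    "REFERENCE_LINKING_HUBS",
]

log = logging.getLogger(__name__)

#: the seven hubs of the packaged reference miRNA→hub map
REFERENCE_LINKING_HUBS = (
    "RXRA", "MAP3K7", "NR3C1", "PABPC1", "NDRG1", "RELA", "CTNNB1",
)


@dataclass(frozen=True)
class OverlayNetwork:
    """Bipartite miRNA↔gene graph restricted to a node set.

    No isolated miRNA nodes: every miRNA present targets at least one
    retained gene.
    """

    mirna_nodes: frozenset[str]
    gene_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def targets_of(self, mirna: str) -> frozenset[str]:
        return frozenset(g for m, g in self.edges if m == mirna)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class HubTargetSummary:
    """Classification of overlay miRNAs by how many hubs each targets."""

    hubs: tuple[str, ...]
    per_mirna: dict  # miRNA -> frozenset of hubs targeted (>= 1)
    per_hub_total: dict  # hub -> count of all miRNAs targeting it
    single_hub_counts: dict  # hub -> count of miRNAs targeting only it
    total_mirnas: int
    multi_hub_mirnas: int

    def to_table(self) -> pd.DataFrame:
        """Two-column table (miRNA, hubs): multi-hub rows first, then
        single-target rows grouped per hub."""
        rows = []
        multi = sorted(
            (m for m, hs in self.per_mirna.items() if len(hs) > 1),
            key=lambda m: (-len(self.per_mirna[m]), m),
        )
        for m in multi:
            rows.append((m, ", ".join(sorted(self.per_mirna[m]))))
        for hub in self.hubs:
            singles = sorted(
                m for m, hs in self.per_mirna.items() if hs == frozenset({hub})
            )
            for m in singles:
                rows.append((m, hub))
        return pd.DataFrame(rows, columns=["mirna", "hubs"])


def build_overlay(
    targets: MiRNATargetMap, node_set: frozenset[str] | set[str]
) -> OverlayNetwork:
    """Restrict a miRNA target map to a node set of interest.

    Edges are (miRNA, gene) pairs with the gene in ``node_set``;
    miRNAs with no retained target are omitted entirely. An empty
    intersection yields an empty overlay with a warning, not an error.
    """
    if not node_set:
        raise ValueError("node set is empty")
    node_set = frozenset(normalize_symbol(g) for g in node_set)
    edges: set[tuple[str, str]] = set()
    for mirna, genes in targets.items():
        for g in genes & node_set:
            edges.add((mirna, g))
    if not edges:
        log.warning("no miRNA targets any node of the given set")
    return OverlayNetwork(
        mirna_nodes=frozenset(m for m, _ in edges),
        gene_nodes=frozenset(g for _, g in edges),
        edges=frozenset(edges),
    )


def summarize_hub_targeting(
    ov: OverlayNetwork, hubs: tuple[str, ...] | list[str]
) -> HubTargetSummary:
    """Classify every overlay miRNA by the number of hubs it targets.

    miRNAs targeting no hub are ignored; hubs targeted by no miRNA are
    allowed and reported with zero counts. The conservation identity
    total = multi-hub + sum(single-hub counts) holds by construction
    and is asserted on every call.
    """
    hubs = tuple(dict.fromkeys(normalize_symbol(h) for h in hubs))
    hubset = frozenset(hubs)
    per_mirna: dict[str, frozenset[str]] = {}
    for m in ov.mirna_nodes:
        hit = ov.targets_of(m) & hubset
        if hit:
            per_mirna[m] = frozenset(hit)
    per_hub_total = {
        h: sum(1 for hs in per_mirna.values() if h in hs) for h in hubs
    }
    single = {
        h: sum(1 for hs in per_mirna.values() if hs == frozenset({h}))
        for h in hubs
    }
    multi = sum(1 for hs in per_mirna.values() if len(hs) > 1)
    total = len(per_mirna)
    assert total == multi + sum(single.values()), "miRNA classification leak"
    return HubTargetSummary(
        hubs=hubs,
        per_mirna=per_mirna,
        per_hub_total=per_hub_total,
        single_hub_counts=single,
        total_mirnas=total,
        multi_hub_mirnas=multi,
    )


def load_reference_hub_targets() -> MiRNATargetMap:
    """Load the packaged miRNA→hub reference map (seven linking hubs)."""
    ref = resources.files("hubnet.data").joinpath("mirna_hub_targets.tsv")
    with resources.as_file(ref) as path:
        return read_mirna_targets(path)
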