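"""Readers and writers for interaction networks, seed lists and miRNA-target maps.

Supported formats (all plain-text, UTF-8, tab-delimited):

* **SIF** — Cytoscape simple interaction format. Each row is either
  ``NODE`` (an isolated node) or ``A<TAB>relation<TAB>B[<TAB>C ...]``,
  which fans out to the edges A–B, A–C, ... The relation token is kept
  on parsed edges but carries no meaning for the topological analyses.
* **TSV edge list** — ``A<TAB>B`` per row; a single-token row declares an
  isolated node so that node sets survive write→read round-trips.
* **Seed list** — one gene symbol per line; ``#`` starts a comment line.
* **miRNA target map** — ``miRNA<TAB>gene`` per row.

Gene symbols are normalized to uppercase, whitespace-stripped tokens
(idempotent, no alias resolution). miRNA identifiers are kept verbatim,
since miRBase-style names are conventionally lowercase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ParseError",
    "SeedSet",
    "MiRNATargetMap",
    "normalize_symbol",
    "read_edge_list",
    "read_seed_list",
    "read_mirna_targets",
    "write_graph",
    "write_mirna_targets",
]

log = logging.getLogger(__name__)

#: relation token used when writing SIF edges
SIF_RELATION = "pp"


class ParseError(ValueError):
    """An input file violates its expected format (message names the line)."""


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Raises ``ValueError`` for empty tokens or tokens with interior
    whitespace. Normalization is idempotent.
    """
    s = symbol.strip().upper()
    if not s:
        raise ValueError(f"empty gene symbol: {symbol!r}")
    if any(c.isspace() for c in s):
        raise ValueError(f"gene symbol contains whitespace: {symbol!r}")
    return s


@dataclass(frozen=True)
class SeedSet:
    """A condition-specific set of seed proteins.

    ``duplicates_removed`` records how many input lines collapsed onto an
    already-seen symbol during normalization.
    """

    condition: str
    members: frozenset[str]
    duplicates_removed: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"seed set {self.condition!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MiRNATargetMap:
    """miRNA identifier -> set of normalized gene symbols."""

    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.mapping.items():
            if not mirna:
                raise ValueError("empty miRNA identifier")
            if not targets:
                raise ValueError(f"miRNA {mirna!r} has an empty target set")

    def __len__(self) -> int:
        return len(self.mapping)

    def __getitem__(self, mirna: str) -> frozenset[str]:
        return self.mapping[mirna]

    def __iter__(self):
        return iter(self.mapping)

    def items(self):
        return self.mapping.items()

    @property
    def genes(self) -> frozenset[str]:
        """All genes targeted by at least one miRNA."""
        out: set[str] = set()
        for targets in self.mapping.values():
            out |= targets
        return frozenset(out)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if fmt not in ("sif", "tsv"):
        raise ValueError(f"unknown graph format: {format!r}")
    return fmt


def read_edge_list(path: str | Path, format: str | None = None) -> nx.Graph:
    """Read an undirected simple graph from a SIF or two-column TSV file.

    Duplicate rows (including reversed duplicates and case variants)
    collapse onto a single edge; self-loops are dropped and counted in a
    logged warning. The returned graph's ``name`` is the file stem.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    g = nx.Graph(name=path.stem)
    n_self_loops = 0
    n_rows = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t") if "\t" in line else line.split()
            try:
                if fmt == "sif":
                    if len(tokens) == 1:
                        g.add_node(normalize_symbol(tokens[0]))
                    elif len(tokens) == 2:
                        raise ValueError(
                            "SIF row with a relation but no target node"
                        )
                    else:
                        a = normalize_symbol(tokens[0])
                        for tok in tokens[2:]:
                            b = normalize_symbol(tok)
                            if a == b:
                                n_self_loops += 1
                                g.add_node(a)
                            else:
                                g.add_edge(a, b)
                else:
                    if len(tokens) == 1:
                        g.add_node(normalize_symbol(tokens[0]))
                    elif len(tokens) == 2:
                        a = normalize_symbol(tokens[0])
                        b = normalize_symbol(tokens[1])
                        if a == b:
                            n_self_loops += 1
                            g.add_node(a)
                        else:
                            g.add_edge(a, b)
                    else:
                        raise ValueError(
                            f"expected 1 or 2 columns, found {len(tokens)}"
                        )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: no usable rows")
    if n_self_loops:
        log.warning(
            "%d self-loop%s removed while reading %s",
            n_self_loops,
            "" if n_self_loops == 1 else "s",
            path,
        )
    g.graph["self_loops_removed"] = n_self_loops
    return g


def read_seed_list(path: str | Path, condition: str) -> SeedSet:
    """Read a one-symbol-per-line seed list into a deduplicated SeedSet."""
    path = Path(path)
    members: set[str] = set()
    duplicates = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                sym = normalize_symbol(line)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if sym in members:
                duplicates += 1
            else:
                members.add(sym)
    if not members:
        raise ParseError(f"{path}: no usable seed symbols")
    if duplicates:
        log.warning("%d duplicate seed(s) removed from %s", duplicates, path)
    return SeedSet(condition=condition, members=frozenset(members),
                   duplicates_removed=duplicates)


def read_mirna_targets(path: str | Path) -> MiRNATargetMap:
    """Read a two-column ``miRNA<TAB>gene`` map; duplicate rows collapse."""
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'miRNA<TAB>gene', "
                    f"found {len(tokens)} column(s)"
                )
            mirna = tokens[0].strip()
            if not mirna:
                raise ParseError(f"{path}:{lineno}: empty miRNA identifier")
            try:
                gene = normalize_symbol(tokens[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            mapping.setdefault(mirna, set()).add(gene)
    if not mapping:
        raise ParseError(f"{path}: no usable rows")
    return MiRNATargetMap(
        mapping={m: frozenset(t) for m, t in mapping.items()}
    )


def _sorted_edges(g: nx.Graph) -> list[tuple[str, str]]:
    return sorted(tuple(sorted(e)) for e in g.edges())


def write_graph(g: nx.Graph, path: str | Path, format: str | None = None) -> None:
    """Write a graph as SIF or TSV so that write→read round-trips.

    Edges are emitted in sorted order; isolated nodes as single-token
    rows (both dialects), so node and edge sets are preserved exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    isolated = sorted(n for n in g.nodes() if g.degree(n) == 0)
    with path.open("w", encoding="utf-8") as fh:
        for a, b in _sorted_edges(g):
            if fmt == "sif":
                fh.write(f"{a}\t{SIF_RELATION}\t{b}\n")
            else:
                fh.write(f"{a}\t{b}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def write_mirna_targets(targets: MiRNATargetMap, path: str | Path) -> None:
    """Write a miRNA target map as a sorted two-column TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for mirna in sorted(targets.mapping):
            for gene in sorted(targets.mapping[mirna]):
                fh.write(f"{mirna}\t{gene}\n")
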