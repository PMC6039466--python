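"""End-to-end pipeline: config validation, orchestration, run report.

A run is described by a single YAML config naming either real input
files (interactome + per-condition seed lists + optional miRNA target
map) or a synthetic-generation block — never both. The pipeline then
executes, per condition, first-order extraction → topology panel →
centralities → hub selection → hub subnetwork; merges the condition
subnetworks; re-analyzes the linking region; and overlays miRNA
targeting on it. Every intermediate artifact is written under the
output directory with fixed names, and a machine-readable
``report.json`` collects every headline quantity, the config echo and
all warnings. Re-running an unchanged config and seed reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

import networkx as nx
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .extraction import extract_first_order
from .hubs import (
    HUB_STRATEGIES,
    SUBNETWORK_STRATEGIES,
    extract_hub_subnetwork,
    select_hubs,
)
from .io import (
    MiRNATargetMap,
    SeedSet,
    read_edge_list,
    read_mirna_targets,
    read_seed_list,
    write_graph,
    write_mirna_targets,
)
from .merge import linking_subnetwork, merge_networks, provenance_report
from .mirna import build_overlay, summarize_hub_targeting
from .synth import (
    SyntheticTruth,
    generate_condition_seeds,
    generate_interactome,
    generate_mirna_targets,
    plant_hubs,
)
from .topology import degree_distribution, fit_power_law, global_stats, node_centralities

__all__ = ["RunConfig", "SyntheticBlock", "InputsBlock",
           "validate_config", "run_pipeline"]

log = logging.getLogger(__name__)


class SyntheticBlock(BaseModel):
    """Synthetic-instance generation parameters (the study conditions)."""

    model_config = ConfigDict(extra="forbid")

    n_nodes: int = 2000
    attachment_m: int = 2
    n_conditions: int = 3
    seeds_per_condition: int = 100
    overlap_fraction: float = 0.2
    hub_bias: bool = True
    n_planted_hubs: int = 8
    hub_boost: float = 5.0
    shared_hub_fraction: float = 0.5
    mirna_count: int = 200
    targets_per_mirna_mean: float = 5.0
    hub_enrichment: float = 0.5


class InputsBlock(BaseModel):
    """Paths to real input files."""

    model_config = ConfigDict(extra="forbid")

    interactome: str
    interactome_format: Optional[str] = None
    seeds: dict[str, str]
    mirna_targets: Optional[str] = None

    @model_validator(mode="after")
    def _paths_exist(self) -> "InputsBlock":
        missing = [
            p
            for p in [self.interactome, *self.seeds.values(),
                      *( [self.mirna_targets] if self.mirna_targets else [] )]
            if not Path(p).exists()
        ]
        if missing:
            raise ValueError(f"input path(s) do not exist: {missing}")
        if not self.seeds:
            raise ValueError("at least one condition seed list is required")
        return self


class RunConfig(BaseModel):
    """Fully validated pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    output_dir: str
    random_seed: int = 0
    n_hubs: int = 8
    hub_strategy: str = "degree_betweenness_borda"
    k_sd: float = 2.0
    subnetwork_strategy: str = "geodesic_union"
    linking_rule: str = "membership"
    keep_isolated_seeds: bool = False
    giant_only: bool = False
    synthetic: Optional[SyntheticBlock] = None
    inputs: Optional[InputsBlock] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        problems = []
        if (self.synthetic is None) == (self.inputs is None):
            problems.append(
                "exactly one of 'synthetic' and 'inputs' must be present "
                "(they are mutually exclusive)"
            )
        if self.hub_strategy not in HUB_STRATEGIES:
            problems.append(f"unknown hub_strategy {self.hub_strategy!r}")
        if self.subnetwork_strategy not in SUBNETWORK_STRATEGIES:
            problems.append(
                f"unknown subnetwork_strategy {self.subnetwork_strategy!r}"
            )
        if self.linking_rule not in ("membership", "bridge"):
            problems.append(f"unknown linking_rule {self.linking_rule!r}")
        if self.n_hubs < 1:
            problems.append("n_hubs must be >= 1")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file.

    Unknown keys are rejected; every problem found is reported at once
    in the raised ``ValidationError``.
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return RunConfig.model_validate(data)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _jsonable(obj):
    """Recursively convert to JSON-clean values (NaN -> null, sets sorted)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    return obj


def _write_seed_list(seeds: SeedSet, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# condition: {seeds.condition}\n")
        for s in sorted(seeds.members):
            fh.write(s + "\n")


def _write_centralities(ct, path: Path) -> None:
    ct.to_csv(path, sep="\t", float_format="%.10g")


def _materialize_inputs(cfg: RunConfig, outdir: Path):
    """Load or generate (interactome, seed sets, miRNA map, truth)."""
    if cfg.inputs is not None:
        blk = cfg.inputs
        interactome = read_edge_list(blk.interactome, blk.interactome_format)
        seed_sets = [
            read_seed_list(path, condition)
            for condition, path in sorted(blk.seeds.items())
        ]
        mirna = (
            read_mirna_targets(blk.mirna_targets)
            if blk.mirna_targets else None
        )
        return interactome, seed_sets, mirna, None

    syn = cfg.synthetic
    base = int(cfg.random_seed)
    interactome = generate_interactome(
        syn.n_nodes, syn.attachment_m, random_seed=base
    )
    planted: list[str] = []
    if syn.n_planted_hubs > 0:
        interactome, planted = plant_hubs(
            interactome, syn.n_planted_hubs, syn.hub_boost,
            random_seed=base + 1,
        )
    # a fraction of the planted hubs forms the shared disease axis (they
    # join the common seed core); the rest are dealt round-robin to
    # individual conditions so each network also has hubs of its own
    n_shared = round(syn.shared_hub_fraction * len(planted))
    shared_hubs = planted[:n_shared]
    own_hubs: dict[int, list[str]] = {i: [] for i in range(syn.n_conditions)}
    for j, hub in enumerate(planted[n_shared:]):
        own_hubs[j % syn.n_conditions].append(hub)
    seed_sets, truth = generate_condition_seeds(
        interactome,
        syn.n_conditions,
        syn.seeds_per_condition,
        syn.overlap_fraction,
        hub_bias=syn.hub_bias,
        random_seed=base + 2,
        must_include=shared_hubs,
    )
    if planted:
        seed_sets = [
            SeedSet(
                condition=ss.condition,
                members=frozenset(ss.members | set(own_hubs[i])),
            )
            for i, ss in enumerate(seed_sets)
        ]
        truth = SyntheticTruth(
            planted_hubs={
                ss.condition: tuple(shared_hubs) + tuple(own_hubs[i])
                for i, ss in enumerate(seed_sets)
            },
            planted_linking=truth.planted_linking,
            generator_params={
                **truth.generator_params,
                "n_planted_hubs": syn.n_planted_hubs,
                "hub_boost": syn.hub_boost,
                "shared_hub_fraction": syn.shared_hub_fraction,
            },
        )
    mirna = generate_mirna_targets(
        interactome,
        syn.mirna_count,
        syn.targets_per_mirna_mean,
        syn.hub_enrichment,
        random_seed=base + 3,
    )
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    write_graph(interactome, inputs_dir / "interactome.sif", "sif")
    for ss in seed_sets:
        _write_seed_list(ss, inputs_dir / f"seeds_{ss.condition}.txt")
    write_mirna_targets(mirna, inputs_dir / "mirna_targets.tsv")
    (inputs_dir / "truth.json").write_text(
        json.dumps(_jsonable(truth.to_dict()), indent=2, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    return interactome, seed_sets, mirna, truth


def _analyze_network(g: nx.Graph, cfg: RunConfig, outdir: Path, label: str):
    """Stats + centralities + hubs + subnetwork for one network."""
    outdir.mkdir(parents=True, exist_ok=True)
    stats = global_stats(g, giant_only=cfg.giant_only)
    ct = node_centralities(g)
    dist = degree_distribution(g)
    try:
        fit = fit_power_law(dist)
        fit_info = {"exponent": fit.exponent, "r_squared": fit.r_squared}
    except ValueError as exc:
        log.warning("%s: power-law fit skipped (%s)", label, exc)
        fit_info = None
    n_hubs = min(cfg.n_hubs, len(ct))
    hub_res = select_hubs(
        ct, n_hubs=n_hubs, strategy=cfg.hub_strategy, k_sd=cfg.k_sd
    )
    subnet = None
    if len(hub_res.hubs) >= 2:
        subnet = extract_hub_subnetwork(
            g, hub_res.hubs, strategy=cfg.subnetwork_strategy
        )
    elif len(hub_res.hubs) == 1:
        subnet = extract_hub_subnetwork(g, hub_res.hubs, strategy="induced")
        log.warning("%s: only one hub; induced singleton subnetwork", label)
    else:
        log.warning("%s: no hubs selected; no subnetwork extracted", label)

    write_graph(g, outdir / "network.sif", "sif")
    _write_centralities(ct, outdir / "centralities.tsv")
    dist.to_csv(outdir / "degree_distribution.tsv", sep="\t", index=False)
    hub_table = hub_res.ranking.head(len(hub_res.hubs)).copy()
    hub_table.insert(0, "rank", range(1, len(hub_table) + 1))
    hub_table.to_csv(outdir / "hubs.tsv", sep="\t", float_format="%.10g")
    if subnet is not None:
        write_graph(subnet.graph, outdir / "hub_subnetwork.sif", "sif")
    (outdir / "stats.json").write_text(
        json.dumps(_jsonable(stats.to_dict()), indent=2, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
    panel = {
        "stats": stats.to_dict(),
        "power_law": fit_info,
        "hubs": list(hub_res.hubs),
        "hub_strategy": hub_res.strategy,
        "hub_parameters": hub_res.parameters,
        "subnetwork": None
        if subnet is None
        else {
            "strategy": subnet.strategy,
            "n_nodes": subnet.graph.number_of_nodes(),
            "n_edges": subnet.graph.number_of_edges(),
        },
    }
    return panel, subnet


def _write_overlay(ov, path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for mirna, gene in sorted(ov.edges):
            fh.write(f"{mirna}\ttargets\t{gene}\n")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline for a validated config.

    Returns the run report (also written to ``<output_dir>/report.json``).
    Any stage failure aborts with an exception naming the stage.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    pkg_logger = logging.getLogger("hubnet")
    pkg_logger.addHandler(collector)
    try:
        report: dict = {
            "tool": "hubnet",
            "version": __version__,
            "config": cfg.model_dump(mode="json"),
            "conditions": {},
            "merge": None,
            "linking": None,
            "overlay": None,
        }
        stage = "inputs"
        try:
            interactome, seed_sets, mirna, truth = _materialize_inputs(
                cfg, outdir
            )
            report["interactome"] = {
                "n_nodes": interactome.number_of_nodes(),
                "n_edges": interactome.number_of_edges(),
            }

            subnets = []
            for ss in seed_sets:
                stage = f"condition:{ss.condition}"
                fonet = extract_first_order(
                    interactome, ss, keep_isolated_seeds=cfg.keep_isolated_seeds
                )
                cond_dir = outdir / "conditions" / ss.condition
                panel, subnet = _analyze_network(
                    fonet.graph, cfg, cond_dir, ss.condition
                )
                panel["seeds_found"] = len(fonet.seeds_found)
                panel["seeds_missing"] = sorted(fonet.seeds_missing)
                panel["seeds_isolated"] = sorted(fonet.seeds_isolated)
                report["conditions"][ss.condition] = panel
                if subnet is not None:
                    subnets.append((ss.condition, subnet))

            linking_nodes = None
            linking_hubs: list[str] = []
            if len(subnets) >= 2:
                stage = "merge"
                merged = merge_networks(subnets, linking_rule=cfg.linking_rule)
                prov = provenance_report(merged)
                write_graph(merged.graph, outdir / "merged.sif", "sif")
                attrs = outdir / "merged_node_attributes.tsv"
                with attrs.open("w", encoding="utf-8") as fh:
                    fh.write("node\tprovenance\tpartition\n")
                    for n in sorted(merged.graph.nodes()):
                        fh.write(
                            f"{n}\t{';'.join(sorted(merged.provenance[n]))}"
                            f"\t{merged.partition[n]}\n"
                        )
                report["merge"] = {
                    "specific_counts": prov["specific_counts"],
                    "linking_count": prov["linking_count"],
                    "total_nodes": prov["total_nodes"],
                    "total_edges": prov["total_edges"],
                    "overlap": prov["overlap"].to_dict(),
                    "linking_rule": cfg.linking_rule,
                }
                stage = "linking"
                if merged.linking_nodes:
                    linking = linking_subnetwork(merged)
                    link_panel, _ = _analyze_network(
                        linking, cfg, outdir / "linking", "linking"
                    )
                    report["linking"] = link_panel
                    linking_nodes = frozenset(linking.nodes())
                    linking_hubs = link_panel["hubs"]
                else:
                    log.warning("linking region empty; linking stage skipped")
            elif len(subnets) == 1:
                log.warning(
                    "only one condition network: merge stage skipped"
                )

            stage = "overlay"
            if mirna is not None and linking_nodes:
                ov = build_overlay(mirna, linking_nodes)
                summary = summarize_hub_targeting(ov, linking_hubs)
                _write_overlay(ov, outdir / "overlay.sif")
                summary.to_table().to_csv(
                    outdir / "overlay_summary.tsv", sep="\t", index=False
                )
                report["overlay"] = {
                    "n_mirnas": len(ov.mirna_nodes),
                    "n_genes": len(ov.gene_nodes),
                    "n_edges": len(ov.edges),
                    "hub_targeting": {
                        "hubs": list(summary.hubs),
                        "total_mirnas": summary.total_mirnas,
                        "multi_hub_mirnas": summary.multi_hub_mirnas,
                        "single_hub_counts": summary.single_hub_counts,
                        "per_hub_total": summary.per_hub_total,
                    },
                }
            elif mirna is not None:
                log.warning(
                    "no linking region available: miRNA overlay skipped"
                )
            if truth is not None:
                report["truth"] = truth.to_dict()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        report["warnings"] = list(collector.messages)
        payload = json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
        (outdir / "report.json").write_text(payload, encoding="utf-8")
        return report
    finally:
        pkg_logger.removeHandler(collector)
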