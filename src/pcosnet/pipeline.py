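"""Config-driven end-to-end orchestration.

Reproduces the whole workflow in one call: build the thresholded interaction
graph from a curated gene table and a STRING-dialect edge table, predict the
minimal novel connectors for orphan seeds, compute topology statistics and
hubs, run over-representation analysis against a GMT collection with BH-FDR
control and weighted set cover, and extract the process-specific subnetwork
with its linking nodes. Configuration is strict: unknown keys are fatal,
because silently ignored typos would make sparse parameter reporting
unverifiable. All randomness funnels through the single config seed.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from . import connector_search, enrichment, graph_core, io_formats, subnetwork

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration with documented defaults."""

    gene_table: str = ""
    edge_table: str = ""
    gene_sets: str = ""
    out_dir: str = "results"
    tau: float = graph_core.DEFAULT_TAU
    prior: float = graph_core.DEFAULT_PRIOR
    channels: list[str] = field(default_factory=lambda: list(io_formats.DEFAULT_CHANNELS))
    hub_threshold: int = graph_core.DEFAULT_HUB_THRESHOLD
    connector_mode: str = "exact"
    max_intermediates: int = connector_search.MAX_DEPTH
    exact_bound: int = connector_search.DEFAULT_EXACT_BOUND
    fdr_threshold: float = enrichment.DEFAULT_FDR_THRESHOLD
    max_sets: int | None = None
    coverage_target: float = 1.0
    universe_size: int | None = None
    subnetwork_tag: str = "fpt_associated"
    pathway_name: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("gene_table", "edge_table", "gene_sets"):
            p = getattr(self, name)
            if not p:
                raise ValueError(f"config key {name!r} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError(f"tau {self.tau} outside (0, 1]")
        if not 0.0 <= self.prior < 1.0:
            raise ValueError(f"prior {self.prior} outside [0, 1)")
        unknown = set(self.channels) - set(io_formats.CHANNELS)
        if not self.channels or unknown:
            raise ValueError(f"invalid channel selection {self.channels}")
        if self.hub_threshold < 1:
            raise ValueError("hub_threshold must be >= 1")
        if self.connector_mode not in ("exact", "greedy"):
            raise ValueError(f"unknown connector_mode {self.connector_mode!r}")
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError(f"fdr_threshold {self.fdr_threshold} outside (0, 1]")
        if not 0.0 < self.coverage_target <= 1.0:
            raise ValueError(f"coverage_target {self.coverage_target} outside (0, 1]")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file.

    Unknown keys are hard errors (catching typos); every field left at its
    default is logged.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    for f in dataclasses.fields(RunConfig):
        if f.name not in raw:
            logger.info("config default applied: %s = %r", f.name, getattr(cfg, f.name))
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    """Everything a completed run produced."""

    config: RunConfig
    graph: nx.Graph
    gene_table: io_formats.GeneTable
    connectors: connector_search.ConnectorResult
    topology: graph_core.TopologySummary
    enrichment_results: list[enrichment.EnrichmentResult]
    cover: enrichment.CoverSelection
    subnetwork: subnetwork.SubnetworkReport
    linking: set[str]
    enrichment_table: object = None  # pandas DataFrame
    summary: dict = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run(config: RunConfig, write: bool = True) -> RunReport:
    """Execute the full pipeline and (optionally) write the result file set."""
    config.validate()
    stage = "load_inputs"
    try:
        genes = io_formats.read_gene_table(config.gene_table)
        edges = io_formats.read_string_links(config.edge_table)
        collection = io_formats.read_gmt(config.gene_sets)

        stage = "build_graph"
        g = graph_core.build_graph(
            edges, genes, tau=config.tau, channels=config.channels, prior=config.prior
        )

        stage = "find_connectors"
        orphans = set(g.nodes) - graph_core.largest_component(g)
        conn = connector_search.find_connectors(
            g,
            orphans,
            edges,
            tau=config.tau,
            channels=config.channels,
            prior=config.prior,
            max_intermediates=config.max_intermediates,
            mode=config.connector_mode,
            exact_bound=config.exact_bound,
        )

        stage = "annotate_novel"
        g = connector_search.annotate_novel(g, conn)

        stage = "topology_summary"
        topo = graph_core.topology_summary(g, hub_threshold=config.hub_threshold)

        stage = "enrichment"
        universe = None
        if config.universe_size is not None:
            universe = _padded_universe(collection, config.universe_size)
        results = enrichment.hypergeom_ora(set(g.nodes), collection, universe=universe)
        significant = enrichment.significant_results(results, config.fdr_threshold)

        stage = "weighted_set_cover"
        cover = enrichment.weighted_set_cover(
            significant, max_sets=config.max_sets, coverage_target=config.coverage_target
        )
        table = enrichment.enrichment_report(results, cover)

        stage = "extract_subnetwork"
        pathway_members: frozenset[str] = frozenset()
        if config.pathway_name is not None:
            if config.pathway_name not in collection.sets:
                raise KeyError(f"pathway {config.pathway_name!r} not in the collection")
            pathway_members = collection.members(config.pathway_name)
        sub = subnetwork.extract_subnetwork(
            g, literature_tag=config.subnetwork_tag, pathway_members=pathway_members
        )

        stage = "linking_nodes"
        linking = subnetwork.linking_nodes(g, sub)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    summary = {
        "n_nodes": topo.n_nodes,
        "n_edges": topo.n_edges,
        "n_novel": len(conn.connectors),
        "n_unresolved_orphans": len(conn.unresolved),
        "average_degree": topo.average_degree_1dp,
        "average_degree_full": topo.average_degree,
        "hubs": [list(h) for h in topo.hub_table],
        "n_significant_pathways": len(significant),
        "selected_pathways": list(cover.selected),
        "subnetwork_nodes": sorted(sub.nodes),
        "linking_nodes": sorted(linking),
        "single_linking_node": sorted(linking)[0] if len(linking) == 1 else None,
        "config": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(RunConfig)
        },
    }
    report = RunReport(
        config=config,
        graph=g,
        gene_table=genes,
        connectors=conn,
        topology=topo,
        enrichment_results=results,
        cover=cover,
        subnetwork=sub,
        linking=linking,
        enrichment_table=table,
        summary=summary,
    )
    if write:
        out_dir = Path(config.out_dir)
        try:
            io_formats.write_results(report, out_dir)
        except Exception as exc:
            # remove partial outputs so a failed run leaves nothing behind
            if out_dir.exists():
                shutil.rmtree(out_dir, ignore_errors=True)
            raise StageError("write_results", exc) from exc
    return report


def _padded_universe(collection: io_formats.GeneSetCollection, size: int) -> set[str]:
    """Pad the annotation universe with placeholder genes up to ``size``,
    emulating a genome-scale reference list."""
    union = set(collection.member_union())
    if size < len(union):
        raise ValueError(
            f"universe_size {size} smaller than the annotated union ({len(union)})"
        )
    pad = [f"REF{i + 1:05d}" for i in range(size - len(union))]
    return union | set(pad)
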