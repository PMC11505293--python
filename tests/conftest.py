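"""Shared fixtures: packaged curated lists and a small synthetic study."""

from __future__ import annotations

import pytest

import pcosnet as p
from pcosnet import io_formats


@pytest.fixture(scope="session")
def curated_genes() -> p.GeneTable:
    return p.load_curated_genes()


@pytest.fixture(scope="session")
def pathways() -> p.GeneSetCollection:
    return p.load_pathways()


@pytest.fixture(scope="session")
def small_spec() -> p.SyntheticSpec:
    """A scaled-down synthetic study used across the suite."""
    return p.SyntheticSpec(
        n_seeds=40,
        n_orphans=8,
        n_connectors=8,
        n_background=16,
        n_fpt=12,
        core_edges=80,
        planted_hub_degree=15,
        n_noise_edges=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_network(small_spec):
    """(gene table, edge records, ground truth) for the small synthetic study."""
    return p.generate_network(small_spec)


@pytest.fixture(scope="session")
def small_run(small_spec, small_network, tmp_path_factory) -> p.RunReport:
    """A full pipeline run on the small synthetic study."""
    genes, edges, _ = small_network
    d = tmp_path_factory.mktemp("small_run")
    io_formats.write_gene_table(genes, d / "genes.tsv")
    io_formats.write_string_links(edges, d / "edges.tsv")
    collection, _ = p.generate_annotation(small_spec, genes.symbols()[: small_spec.study_size])
    io_formats.write_gmt(collection, d / "sets.gmt")
    cfg = p.RunConfig(
        gene_table=str(d / "genes.tsv"),
        edge_table=str(d / "edges.tsv"),
        gene_sets=str(d / "sets.gmt"),
        out_dir=str(d / "out"),
        seed=small_spec.seed,
    )
    return p.run(cfg)


def make_records(edges) -> list[p.EdgeRecord]:
    """Edge records from (a, b, score) triples, single experiments channel."""
    return [
        p.EdgeRecord.make(a, b, {"experiments": s}, combined_score=s) for a, b, s in edges
    ]
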