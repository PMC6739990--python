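"""Shared fixtures: toy graphs, a small synthetic bundle, and a pinned
default-scale run used by the slower end-to-end tests."""

from __future__ import annotations

import networkx as nx
import pytest

from enchain.chains import RegulatoryNetwork
from enchain.elements import GenomicInterval, RegulatoryElement
from enchain.pipeline import PipelineConfig, run_pipeline
from enchain.simulate import SyntheticConfig, write_fixture_bundle


def make_network(edges, promoters, network_id="net0", chrom="chr1"):
    """Build a RegulatoryNetwork from an edge list; nodes not listed as
    promoters are enhancers."""
    g = nx.Graph()
    g.add_edges_from(edges)
    for n in g.nodes:
        g.nodes[n]["kind"] = "promoter" if n in promoters else "enhancer"
    return RegulatoryNetwork(network_id=network_id, graph=g, chrom=chrom, span=0)


def make_promoter(element_id, chrom="chr1", tss=100_000, gene_id=None, strand="+"):
    start, end = (tss - 1500, tss + 500) if strand == "+" else (tss - 500, tss + 1500)
    return RegulatoryElement(
        element_id=element_id,
        interval=GenomicInterval(chrom, start, end, strand),
        kind="promoter",
        gene_id=gene_id or element_id,
        tss=tss,
    )


def make_enhancer(element_id, center, chrom="chr1"):
    return RegulatoryElement(
        element_id=element_id,
        interval=GenomicInterval(chrom, center - 200, center + 200),
        kind="enhancer",
    )


SMALL_CONFIG = dict(
    seed=7,
    n_chromosomes=1,
    chrom_length=3_000_000,
    n_genes=30,
    n_enhancers=15,
    n_planted_chains=10,
    n_low_expressed=15,
    n_single_enhancer_genes=3,
    n_indirect_genes=2,
    tissue_panel=("T1", "T2"),
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A one-chromosome, two-tissue bundle for fast end-to-end tests."""
    directory = tmp_path_factory.mktemp("small_bundle")
    config = SyntheticConfig(**SMALL_CONFIG)
    manifest = write_fixture_bundle(config, directory)
    return config, directory, manifest


@pytest.fixture(scope="session")
def small_report(small_bundle, tmp_path_factory):
    config, directory, _ = small_bundle
    out = tmp_path_factory.mktemp("small_out")
    pc = PipelineConfig(bundle_dir=str(directory), out_dir=str(out), seed=config.seed)
    return pc, run_pipeline(pc)


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default study conditions (50 planted chains, beta = 5), pinned seed."""
    directory = tmp_path_factory.mktemp("default_bundle")
    config = SyntheticConfig(seed=11)
    write_fixture_bundle(config, directory)
    return config, directory


@pytest.fixture(scope="session")
def default_report(default_bundle, tmp_path_factory):
    config, directory = default_bundle
    out = tmp_path_factory.mktemp("default_out")
    pc = PipelineConfig(bundle_dir=str(directory), out_dir=str(out), seed=config.seed)
    return pc, run_pipeline(pc)
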