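"""Shared fixtures: one session-scoped simulated dataset and its derived
per-genome products, so expensive simulation runs once."""

from __future__ import annotations

import pytest

from rgenes.duplication import detect_tandem_arrays, homology_clusters, to_r_loci
from rgenes.rgene_catalog import select_nbs_genes
from rgenes.synthetic_data import SimulationConfig, simulate_genomes


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_genomes(sim_config)


@pytest.fixture(scope="session")
def genome_products(dataset):
    """Per-genome R records, arrays and loci computed with defaults."""
    out = {}
    for name in dataset.genome_names:
        g = dataset.genomes[name]
        clusters = homology_clusters(dataset.blast_within[name])
        arrays = detect_tandem_arrays(g.models, clusters)
        records = select_nbs_genes(g.domains, g.models)
        loci, stats = to_r_loci(records, arrays)
        out[name] = {
            "records": records,
            "arrays": arrays,
            "loci": loci,
            "stats": stats,
        }
    return out


@pytest.fixture(scope="session")
def written_dataset(dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simfiles")
    paths = dataset.write(outdir)
    return outdir, paths
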