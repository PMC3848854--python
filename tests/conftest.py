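import pytest

from paseq import (CallerParams, SimulationConfig, assign_categories,
                   call_pa_clusters, matrix_from_clusters, simulate_dataset)

#: single fixed seed for the shared default-scale simulation
SIM_SEED = 1


@pytest.fixture(scope="session")
def sim():
    """Default-scale synthetic dataset (300 genes, 13 tissues)."""
    return simulate_dataset(SimulationConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def small_sim():
    """Quick small dataset for tests that do not need default scale."""
    cfg = SimulationConfig(seed=7, n_contigs=1, contig_length=400_000,
                           n_genes=40, n_artifact_sites=6,
                           n_overlapping_gene_pairs=2)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def called(sim):
    return call_pa_clusters(sim.profile, CallerParams(), sim.genome)


@pytest.fixture(scope="session")
def assignments(sim, called):
    return assign_categories(called, sim.genes)


@pytest.fixture(scope="session")
def matrix(sim, called):
    return matrix_from_clusters(called, sim.tissues,
                                sim.profile.library_sizes())
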