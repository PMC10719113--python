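import numpy as np
import pytest

from mcatlas.sim import (SimulationConfig, simulate_contacts,
                         simulate_expression_profiles, simulate_methylomes,
                         simulate_motif_dmrs, simulate_subclass_profiles)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_cells=120, n_clusters=3, chrom_size=10_000_000,
                            seed=1)


@pytest.fixture(scope="session")
def methylome(small_config):
    return simulate_methylomes(small_config)


@pytest.fixture(scope="session")
def k4_config():
    return SimulationConfig(n_cells=300, n_clusters=4, chrom_size=20_000_000,
                            seed=2)


@pytest.fixture(scope="session")
def k4_methylome(k4_config):
    return simulate_methylomes(k4_config)


@pytest.fixture(scope="session")
def contact_config():
    # clean checkerboard: no domains/loops confounding compartments
    return SimulationConfig(n_cells=24, n_clusters=2, chrom_size=20_000_000,
                            contact_resolution=100_000, contacts_per_cell=30_000,
                            n_compartment_blocks=6, domain_size_bins=100_000,
                            n_loops=0, seed=3)


@pytest.fixture(scope="session")
def contact_set(contact_config):
    _, truth = simulate_methylomes(contact_config)
    return simulate_contacts(contact_config, truth) + (contact_config,)


@pytest.fixture(scope="session")
def domain_config():
    return SimulationConfig(n_cells=16, n_clusters=2, chrom_size=10_000_000,
                            contact_resolution=100_000, contacts_per_cell=40_000,
                            n_compartment_blocks=1, domain_size_bins=20,
                            n_loops=0, seed=4)


@pytest.fixture(scope="session")
def domain_contacts(domain_config):
    _, truth = simulate_methylomes(domain_config)
    return simulate_contacts(domain_config, truth) + (domain_config,)


@pytest.fixture(scope="session")
def expression(small_config, methylome):
    _, truth = methylome
    return simulate_expression_profiles(small_config, truth)


@pytest.fixture(scope="session")
def grn_world(small_config, methylome):
    _, truth = methylome
    seqs, pwms = simulate_motif_dmrs(small_config, truth, n_regulons=3,
                                     n_dmrs=200)
    profiles = simulate_subclass_profiles(small_config, truth, n_subclasses=30)
    return {"truth": truth, "seqs": seqs, "pwms": pwms, "profiles": profiles}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
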