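import pytest

from ampligen.models import Allele, AlleleCatalog
from ampligen.simulate import (SimulationConfig, simulate_allele_pool,
                               simulate_genotypes, simulate_reads)


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured simulation: 3 populations, pseudogene on."""
    return SimulationConfig(
        seed=7,
        n_populations=3,
        individuals_per_population=(10, 5, 3),
        n_alleles_pool=12,
        n_loci=4,
        depth_mean=150.0,
        depth_sd=40.0,
    )


@pytest.fixture(scope="session")
def small_pool(small_config):
    return simulate_allele_pool(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_pool):
    return simulate_genotypes(small_pool, small_config)


@pytest.fixture(scope="session")
def small_reads(small_config, small_truth):
    return simulate_reads(small_truth, small_config)


@pytest.fixture(scope="session")
def noise_free_run():
    """No-noise simulation bundle: (config, pool, truth, reads)."""
    config = SimulationConfig(
        seed=11,
        n_populations=2,
        individuals_per_population=(8, 4),
        n_alleles_pool=10,
        n_loci=3,
        depth_mean=120.0,
        depth_sd=20.0,
        point_error_rate=0.0,
        chimera_rate=0.0,
    )
    pool = simulate_allele_pool(config)
    truth = simulate_genotypes(pool, config)
    reads = simulate_reads(truth, config)
    return config, pool, truth, reads


@pytest.fixture
def tiny_catalog():
    return AlleleCatalog([
        Allele(name="A*01", nt="ATGGCTAAA"),
        Allele(name="A*02", nt="ATGGCGAAA"),
        Allele(name="A*03", nt="ATGTCTAAA"),
    ])
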