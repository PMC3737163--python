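import numpy as np
import pytest

from ashcomp.simulate import SimulationConfig, derive_species, derive_strain, generate_ancestor

SMALL_TANDEMS = [("famCWP1", 4, 4), ("famRAI1", 2, 1)]


def small_config(seed=11, **kw):
    defaults = dict(
        seed=seed, n_chromosomes=3, chrom_length=30_000, depth=20,
        mate_depth=8, tandem_events=list(SMALL_TANDEMS),
        seq_error_rate_by_quality_class=(0.0, 0.0, 0.0, 0.0),
        n_translocations=2,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def sim_config():
    return small_config()


@pytest.fixture(scope="session")
def ancestor(sim_config):
    return generate_ancestor(sim_config)


@pytest.fixture(scope="session")
def strain_pair(ancestor, sim_config):
    strain_a, _ = derive_strain(ancestor, sim_config, "A")
    strain_b, truth = derive_strain(ancestor, sim_config, "B")
    return strain_a, strain_b, truth


@pytest.fixture(scope="session")
def species_pair(ancestor, sim_config):
    species, truth = derive_species(ancestor, sim_config)
    return species, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
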