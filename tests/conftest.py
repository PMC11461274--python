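import numpy as np
import pytest

from repadapt.repeatability import EmpiricalNull, PicMinConfig, build_empirical_null
from repadapt.synthetic import SimulationConfig, simulate_gea_dataset


@pytest.fixture(scope="session")
def null_store() -> EmpiricalNull:
    """Shared empirical null for species counts 20-25 (moderate size)."""
    cfg = PicMinConfig(min_species=20, max_species=25, null_size=200_000, n_eff_sims=20_000, seed=101)
    return build_empirical_null(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic study reused across module tests."""
    cfg = SimulationConfig(
        n_species=22,
        species_presence=(20, 22),
        n_orthogroups=150,
        n_variables=5,
        n_sites_per_species=15,
        adaptive_fraction=0.1,
        n_contributing_species=8,
        seed=7,
    )
    return simulate_gea_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
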