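import numpy as np
import pytest

from frostmas import phenotype as ph
from frostmas import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """A reduced-genome study configuration for fast unit tests."""
    return sim.SimulationConfig(seed=42, n_neutral_variants=1500)


@pytest.fixture(scope="session")
def small_population(small_config):
    return sim.simulate_population(small_config)


@pytest.fixture(scope="session")
def small_study(small_population):
    """Population plus phenotypes, AS table and extreme pools."""
    pop = small_population
    phen = sim.simulate_phenotypes(pop)
    as_env = ph.as_table(phen)
    ranking = as_env.loc[pop.progeny_ids].mean(axis=1)
    rp, sp = ph.build_extreme_pools(
        ranking, pop.pedigree, 30, pop.tolerant_parent_ids
    )
    return {
        "population": pop,
        "phenotypes": phen,
        "as_env": as_env,
        "ranking": ranking,
        "rp": rp,
        "sp": sp,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
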