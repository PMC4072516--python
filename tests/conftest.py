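import numpy as np
import pytest

from paleoline.simulate import (FamilySpec, SimulationParams, query_region,
                                simulate_genome)


@pytest.fixture(scope="session")
def small_sim():
    """One family, 3 kb master, 150 copies at 8% age, 2x reads.

    Session-scoped: several modules reuse it for detection, walking and
    pipeline checks.
    """
    params = SimulationParams(
        master_length=3000,
        family_schedule=[FamilySpec(0.0, ((0.08, 150),))],
        rng_seed=42)
    masters, loci, reads = simulate_genome(params, background_length=60_000)
    return params, masters, loci, reads


@pytest.fixture(scope="session")
def small_query(small_sim):
    _, masters, _, _ = small_sim
    return query_region(masters[0], 575)


@pytest.fixture(scope="session")
def two_family_sim():
    """Two families 5% apart, each one burst; for assignment tests."""
    params = SimulationParams(
        master_length=3000,
        family_schedule=[FamilySpec(0.0, ((0.05, 120),)),
                         FamilySpec(0.05, ((0.05, 120),))],
        rng_seed=43)
    masters, loci, reads = simulate_genome(params, background_length=60_000)
    return params, masters, loci, reads


def random_dna(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
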