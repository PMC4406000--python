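import pytest

from pggtwin import (
    Population,
    StrategyProfile,
    SyntheticConfig,
    TwinPair,
    generate_twin_population,
    make_fixture,
)


@pytest.fixture(scope="session")
def oracle_pop() -> Population:
    """8 fixed heterogeneous profiles, small enough to enumerate exactly."""
    return make_fixture("eightperson_oracle")


@pytest.fixture(scope="session")
def mixed_pop() -> Population:
    """Small synthetic twin population with default generating structure."""
    pop, _ = generate_twin_population(SyntheticConfig(n_mz=30, n_dz=10, seed=42))
    return pop


@pytest.fixture()
def flat_profile() -> StrategyProfile:
    return StrategyProfile("flat", 5, {k: 5 for k in range(21)}, "study2")


def pair_up(profiles, zygosity="MZ"):
    """Pair consecutive profiles into complete twin pairs."""
    pairs = []
    ids = [p.individual_id for p in profiles]
    for j in range(0, len(ids) - 1, 2):
        pairs.append(TwinPair(f"pr{j:03d}", zygosity, (ids[j], ids[j + 1])))
    if len(ids) % 2:
        pairs.append(TwinPair("prlast", zygosity, (ids[-1],)))
    return pairs
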