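import pytest

from spatialeqtl import SimulationConfig, simulate_focal_study, simulate_study

# desk-scale study conditions reused across test modules; session-scoped
# because generation is the expensive step and every consumer is read-only


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=3, n_chromosomes=2, chromosome_length=120_000, n_genes=40,
        n_variants=300, n_samples=50, n_tissues=2,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def focal_study():
    """Full default-scale focal-gene study with a planted co-regulated hub."""
    return simulate_focal_study(seed=1)
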