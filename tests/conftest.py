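import pytest
from hypothesis import HealthCheck, settings

from pairgenome.simpair import SimConfig, derive_pair, generate_ancestor, simulate_depth

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A compact genome pair carrying every event category."""
    return SimConfig(
        seed=11,
        n_chromosomes=2,
        chrom_length=600_000,
        snp_rate=0.001,
        n_shared=3,
        n_insertions_A=3,
        n_insertions_B=2,
        n_eliminations=1,
        gap_spec=[(2000, 100_000)],
        telomere_copies_range=(120, 300),
        min_event_spacing=22_000,
    )


@pytest.fixture(scope="session")
def small_pair(small_config):
    ancestor = generate_ancestor(small_config)
    genome_a, genome_b, truth = derive_pair(ancestor, small_config)
    return ancestor, genome_a, genome_b, truth


@pytest.fixture(scope="session")
def small_depths(small_pair):
    _, genome_a, genome_b, truth = small_pair
    return simulate_depth(genome_a, truth, "A"), simulate_depth(genome_b, truth, "B")
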