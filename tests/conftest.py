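import pytest

from germchrom.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A fast synthetic study: one 200 kb chromosome, shallow libraries."""
    return SyntheticConfig(
        n_chromosomes=1,
        chrom_length=200_000,
        state_mean_length=10_000,
        ip_depth=20_000,
        input_depth=20_000,
        genes_per_class=50,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)
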