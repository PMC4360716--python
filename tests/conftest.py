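import pytest

from viroclade.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A modest diverged community: 3 clades x 2 genomes, error-free reads."""
    return simulate(
        SimConfig(
            seed=11,
            host_len=20_000,
            n_clades=3,
            genomes_per_clade=2,
            n_reads=60,
            read_len=200,
            read_error=0.0,
        )
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-divergence community: every genome identical to the root, so
    marker screening and gene sharing have exact expectations."""
    return simulate(
        SimConfig(
            seed=7,
            host_len=12_000,
            n_clades=2,
            genomes_per_clade=2,
            within_clade_div=0.0,
            between_clade_div=0.0,
            n_reads=10,
        )
    )
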