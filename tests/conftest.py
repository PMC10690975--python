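import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_single_hap_community():
    """Error-free single-haplotype community with clean reads."""
    from haplec.simulate import simulate_haplotypes, simulate_reads, ReadSimParams

    truth = simulate_haplotypes(20_000, 1, 0.0, seed=7)
    long_reads, short_reads, placements = simulate_reads(
        truth,
        ReadSimParams(long_mean_len=6000, long_err_rate=0.0,
                      short_err_rate=0.0, seed=8),
    )
    return truth, long_reads, short_reads, placements


@pytest.fixture(scope="session")
def two_strain_community():
    """Two strains at ~2% pairwise divergence, 10x/10x hybrid reads."""
    from haplec.simulate import simulate_haplotypes, simulate_reads, ReadSimParams

    truth = simulate_haplotypes(30_000, 2, 0.01, indel_fraction=0.1, seed=21)
    long_reads, short_reads, placements = simulate_reads(
        truth, ReadSimParams(long_mean_len=8000, seed=22))
    return truth, long_reads, short_reads, placements
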