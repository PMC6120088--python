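import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

from mirbench import build_equimolar_pool, sample_bias_profile, simulate_library


@pytest.fixture(scope="session")
def small_pool():
    """50 distinct references, equimolar."""
    return build_equimolar_pool(50, seed=11)


@pytest.fixture(scope="session")
def mid_pool():
    """963 distinct references, the standard benchmark pool size."""
    return build_equimolar_pool(963, seed=11)


@pytest.fixture(scope="session")
def unbiased_library(small_pool):
    """A small library with no ligation or PCR bias and no dimers."""
    profile = sample_bias_profile(
        small_pool, sigma_log2=0.0, gc_pcr_slope=0.0, dimer_rate=0.0, seed=5
    )
    return simulate_library(small_pool, profile, depth=100_000, seed=7)


@pytest.fixture(scope="session")
def biased_library(small_pool):
    """A small library with strong ligation bias."""
    profile = sample_bias_profile(
        small_pool, sigma_log2=3.0, gc_pcr_slope=0.3, dimer_rate=0.01, seed=5
    )
    return simulate_library(small_pool, profile, depth=100_000, seed=7)
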