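import numpy as np
import pytest

from dmrscan.simulate import (SyntheticSpec, generate_genome,
                              signature_catalog)


@pytest.fixture(scope="session")
def small_spec():
    """Small synthetic genome: 2 x 400 kb, 8 planted DMR runs."""
    return SyntheticSpec(seed=11, chromosome_lengths=(400_000, 400_000),
                         n_dmr_runs=8)


@pytest.fixture(scope="session")
def small_genome(small_spec):
    return generate_genome(small_spec)


@pytest.fixture(scope="session")
def small_catalog(small_spec):
    return signature_catalog(small_spec)


@pytest.fixture(scope="session")
def scan_run():
    """Full end-to-end scan on the default study conditions (cached)."""
    from dmrscan.benchmarks import scan_benchmark

    return scan_benchmark(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
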