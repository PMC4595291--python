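"""Shared fixtures.

The three-species identification benchmark (image generation + feature
extraction + repeated-split evaluation) is the expensive part of the suite,
so its results are computed once per session and shared.
"""

import pytest

from leaftooth.experiments import species_benchmark

BENCHMARK_SEED = 123


@pytest.fixture(scope="session")
def benchmark_results():
    """(report, permuted_report, X, y) of the seeded species benchmark."""
    return species_benchmark(seed=BENCHMARK_SEED)
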