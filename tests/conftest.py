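import pytest

from ionml import SyntheticSpec, gen_benchmark


@pytest.fixture(scope="session")
def bench221():
    """Benchmark-shaped synthetic dataset (221 proteins, default marginals)."""
    return gen_benchmark(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def truth221(bench221):
    return bench221.truth_map()
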