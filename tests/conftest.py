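import pytest

from triadkit import simulate


@pytest.fixture(scope="session")
def refs():
    return simulate.default_refs()


@pytest.fixture
def small_cfg():
    return simulate.SimConfig(seed=11, n_reads=40, error_rate=0.0)
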