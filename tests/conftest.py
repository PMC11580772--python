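import pytest

from bondtrace.synthetic import (
    Study1Config,
    Study2Config,
    gen_study1,
    gen_study2,
)


@pytest.fixture(scope="session")
def study1_data():
    """Default small-cage dataset (null effect) with its ledger."""
    return gen_study1(Study1Config(seed=11))


@pytest.fixture(scope="session")
def study2_full():
    """Full-size flight-cage dataset: 20 bats, 3 sites, 190 pairs."""
    return gen_study2(Study2Config(seed=5))


@pytest.fixture(scope="session")
def study2_small():
    """Reduced flight-cage dataset for fast model fits."""
    return gen_study2(Study2Config(seed=7, n_bats=12, n_forced_trios=3))
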