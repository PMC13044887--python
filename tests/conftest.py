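import numpy as np
import pytest

from taqsim import (
    InitialConditions,
    PCRSetup,
    ProtocolConfig,
    build_rate_constants,
    make_assay,
)

ANNEAL_T = 60.0 + 273.15


@pytest.fixture(scope="session")
def assay():
    """One synthetic assay reused across the suite (deterministic)."""
    return make_assay(seed=7)


@pytest.fixture(scope="session")
def rates(assay):
    """Realistic association rate: k_on = 1e6 /M/s, kr_on = 1e7 /M/s."""
    return build_rate_constants(assay.sequences, ANNEAL_T, 1e6, 1e7)


@pytest.fixture(scope="session")
def rates_slow(assay):
    """Visualization regime: deliberately low k_on = 1e4 /M/s."""
    return build_rate_constants(assay.sequences, ANNEAL_T, 1e4, 1e7)


@pytest.fixture(scope="session")
def protocol60():
    return ProtocolConfig(n_cycles=60)


@pytest.fixture(scope="session")
def setup60(rates, protocol60):
    """The reference single-assay scenario: 60 cycles, primers 450 nM,
    probe 150 nM, no enzyme decay."""
    return PCRSetup(rates=rates, protocol=protocol60)


@pytest.fixture
def template_ic():
    return InitialConditions(template=1e7)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
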