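import numpy as np
import pytest

from b2arsim import (
    AGONISTS,
    LigandEnvironment,
    Protocol,
    ProtocolSegment,
    RateSet,
    build_standard_protocol,
    naive_state,
)


@pytest.fixture(scope="session")
def rates():
    return RateSet()


@pytest.fixture(scope="session")
def iso_1uM():
    return LigandEnvironment(AGONISTS["isoproterenol"], 1000.0)


@pytest.fixture(scope="session")
def y0():
    return naive_state()


@pytest.fixture(scope="session")
def standard_protocols():
    """The six standard stimulation protocols at a coarse sampling grid."""
    return {
        name: build_standard_protocol(name, "isoproterenol", 1000.0, sample_interval=0.05)
        for name in (
            "phosphorylation",
            "dephosphorylation",
            "internalization",
            "recycling",
            "desensitization",
            "resensitization",
        )
    }


def random_rate_table(rng: np.random.Generator) -> dict:
    """A resolved rate table with each constant scaled log-uniformly 0.1-10x."""
    from b2arsim.network import effective_rates

    base = effective_rates(RateSet(), LigandEnvironment(AGONISTS["ISO"], 1000.0))
    return {k: v * 10 ** rng.uniform(-1, 1) for k, v in base.items()}


def random_state(rng: np.random.Generator) -> np.ndarray:
    """A random valid state vector summing to 1."""
    return rng.dirichlet(np.ones(10))
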