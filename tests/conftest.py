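import numpy as np
import pytest

from esntsc.reservoir import ReservoirSpec, build_reservoir
from esntsc.synthetic import CohortGenSpec, RegularGenSpec, gen_cohort, gen_regular


@pytest.fixture(scope="session")
def small_spec():
    return ReservoirSpec(M=10, a=0.9, rho=0.95, k=1, seed=42)


@pytest.fixture(scope="session")
def small_weights(small_spec):
    return build_reservoir(small_spec)


@pytest.fixture(scope="session")
def burst_data():
    """2-class regular dataset: class 2 carries a variance burst."""
    return gen_regular(RegularGenSpec(seed=11))


@pytest.fixture(scope="session")
def cohort():
    """Small screening-style cohort for unit tests."""
    return gen_cohort(CohortGenSpec(N=80, seed=11))
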