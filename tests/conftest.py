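import numpy as np
import pytest

from txasim import PopPKParameters, SamplingGrid, Subject


@pytest.fixture(scope="session")
def params():
    return PopPKParameters()


@pytest.fixture(scope="session")
def grid():
    return SamplingGrid()


@pytest.fixture
def reference_subject():
    """Reference covariates (70 kg, PLT 196, NIRS 88, IL-8 1), zero etas."""
    return Subject(id="ref", weight=70.0, plt=196.0, nirs=88.0, il8=1.0)


@pytest.fixture
def adult_median_subject():
    """Trial-median adult covariates, zero etas."""
    return Subject(id="adult", weight=80.1, plt=197.0, nirs=88.0, il8=20.3)


@pytest.fixture
def pediatric_subject():
    """A mid-range pediatric trauma subject, zero etas."""
    return Subject(id="ped", weight=38.0, plt=319.0, nirs=65.5, il8=28.4)


def random_individuals(n, seed=0):
    """Random positive two-compartment parameter sets spanning wide scales."""
    rng = np.random.default_rng(seed)
    from txasim import IndividualParameters
    out = []
    for _ in range(n):
        out.append(IndividualParameters(
            cl=rng.uniform(20.0, 600.0),
            v1=rng.uniform(2_000.0, 40_000.0),
            q=rng.uniform(5.0, 500.0),
            v2=rng.uniform(1_000.0, 30_000.0)))
    return out
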