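import numpy as np
import pytest

from fiberplast import BoundarySpec, ElasticParams, build_triangular_lattice, dilute


@pytest.fixture
def elastic():
    return ElasticParams()


@pytest.fixture
def small_diluted():
    """A 10x10 free-boundary network at p = 0.7, fixed seed."""
    return dilute(build_triangular_lattice(10, 10), 0.7, seed=11)


@pytest.fixture
def bulk_boundary():
    return BoundarySpec(left="periodic", right="periodic", top="fixed", bottom="fixed")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
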