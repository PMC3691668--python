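import numpy as np
import pytest

from falcongo.dag import load_dag
from falcongo.fixtures import fixture_dag_6, fixture_dag_15

# 4-node diamond: x1 root; x2, x3 children; x4 requires both x2 and x3.
DIAMOND_EDGES = [("x2", "x1"), ("x3", "x1"), ("x4", "x2"), ("x4", "x3")]


@pytest.fixture(scope="session")
def diamond_dag():
    return load_dag(DIAMOND_EDGES)


@pytest.fixture(scope="session")
def chain_dag():
    # a -> b -> c -> d (a is root)
    return load_dag([("b", "a"), ("c", "b"), ("d", "c")])


@pytest.fixture(scope="session")
def dag6():
    return fixture_dag_6()


@pytest.fixture(scope="session")
def dag15():
    return fixture_dag_15()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
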