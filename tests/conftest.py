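import numpy as np
import pytest

from aviannet import Connectome, pigeon_connectome


@pytest.fixture(scope="session")
def pigeon() -> Connectome:
    return pigeon_connectome()


@pytest.fixture
def three_cycle() -> Connectome:
    return Connectome.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def path_abc() -> Connectome:
    return Connectome.from_edges([("a", "b"), ("b", "c")])


def complete_digraph(n: int) -> Connectome:
    A = np.ones((n, n), dtype=np.int8)
    np.fill_diagonal(A, 0)
    return Connectome(tuple(f"v{i}" for i in range(n)), A)


def random_digraph(n: int, p: float, rng: np.random.Generator) -> Connectome:
    A = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(A, 0)
    return Connectome(tuple(f"v{i}" for i in range(n)), A)


@pytest.fixture
def k4() -> Connectome:
    return complete_digraph(4)
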