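import pytest

from ppidom.graph_io import Network


def path_graph(n: int) -> Network:
    return Network.from_edges([(str(i), str(i + 1)) for i in range(n - 1)])


def cycle_graph(n: int) -> Network:
    return Network.from_edges(
        [(str(i), str((i + 1) % n)) for i in range(n)]
    )


def star_graph(leaves: int) -> Network:
    """K_{1,leaves} with center 'c'."""
    return Network.from_edges([("c", f"l{i}") for i in range(leaves)])


@pytest.fixture
def path4() -> Network:
    return path_graph(4)


@pytest.fixture
def cycle4() -> Network:
    return cycle_graph(4)


@pytest.fixture
def star5() -> Network:
    return star_graph(4)


@pytest.fixture
def two_stars() -> Network:
    edges = [("c1", f"a{i}") for i in range(3)] + [("c2", f"b{i}") for i in range(3)]
    return Network.from_edges(edges)
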