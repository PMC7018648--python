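import pytest

from remedynet import two_recipe_fixture
from remedynet.netbuild import UnweightedNetwork


@pytest.fixture
def two_recipe_corpus():
    """The two printed worked-example recipes (eye ointment + mouthwash)."""
    return two_recipe_fixture()


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques: canonical graph with optimum q = 0.5."""
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
    return UnweightedNetwork(nodes=[f"n{i}" for i in range(8)], edges=edges)


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by one bridge edge (m = 7)."""
    return UnweightedNetwork(
        nodes=list("abcdef"),
        edges=[(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)],
    )
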