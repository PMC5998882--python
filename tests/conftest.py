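import numpy as np
import pytest

from fpe.data_io import (
    ComplexCatalog,
    EssentialSet,
    ExpressionMatrix,
    ProteinNetwork,
    SubcellularData,
)


@pytest.fixture
def triangle():
    return ProteinNetwork(edges=[("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def path3():
    return ProteinNetwork(edges=[("a", "b"), ("b", "c")])


@pytest.fixture
def star5():
    return ProteinNetwork(edges=[("hub", f"leaf{k}") for k in range(5)])


@pytest.fixture
def k4():
    nodes = ["a", "b", "c", "d"]
    return ProteinNetwork(
        edges=[(i, j) for n, i in enumerate(nodes) for j in nodes[n + 1:]]
    )


def random_network(rng: np.random.Generator, n: int, p: float) -> ProteinNetwork:
    """Erdős–Rényi-style simple graph over string IDs."""
    ids = [f"n{k:03d}" for k in range(n)]
    net = ProteinNetwork(nodes=ids)
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                net.add_edge(ids[a], ids[b])
    return net


@pytest.fixture
def tiny_biology():
    """Hand-sized five-input bundle with values checkable by hand.

    Triangle a-b-c plus pendant d; all profiles identical (PCC = 1) except d
    which has no profile; two essentials annotated Nuc/Cyt.
    """
    network = ProteinNetwork(edges=[("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
    expr = ExpressionMatrix(
        profiles={p: np.array([1.0, 2.0, 3.0, 4.0]) for p in "abc"}, T=4
    )
    subcell = SubcellularData(
        records={("e1", "Nuc"), ("e1", "Cyt"), ("e2", "Nuc"),
                 ("a", "Nuc"), ("b", "Cyt"), ("c", "Nuc"), ("c", "Cyt")}
    )
    complexes = ComplexCatalog(
        complexes=[frozenset({"a", "b", "c"}), frozenset({"c", "d"})]
    )
    essential = EssentialSet(members={"e1", "e2", "a"})
    return network, expr, subcell, complexes, essential
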