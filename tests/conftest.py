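import numpy as np
import pytest

from cminet.network import (
    Direction,
    DysregulationEdge,
    SignedBipartiteNetwork,
    TransactionDatabase,
)


@pytest.fixture
def toy_db() -> TransactionDatabase:
    """Four transactions over three items; worked-example database."""
    return TransactionDatabase(
        {
            "t1": frozenset("abc"),
            "t2": frozenset("ab"),
            "t3": frozenset("bc"),
            "t4": frozenset("a"),
        }
    )


@pytest.fixture
def small_network() -> SignedBipartiteNetwork:
    edges = [
        DysregulationEdge("c1", "a", Direction.UP),
        DysregulationEdge("c1", "b", Direction.DOWN),
        DysregulationEdge("c2", "a", Direction.UP),
    ]
    return SignedBipartiteNetwork(["c1", "c2"], ["a", "b"], edges)


def random_network(
    rng: np.random.Generator,
    n_cancers: int = 6,
    n_mirnas: int = 15,
    density: float = 0.3,
) -> SignedBipartiteNetwork:
    """Small random signed bipartite network for property tests."""
    cancers = [f"c{i}" for i in range(n_cancers)]
    mirnas = [f"m{i}" for i in range(n_mirnas)]
    edges = []
    for c in cancers:
        for m in mirnas:
            if rng.random() < density:
                d = Direction.UP if rng.random() < 0.5 else Direction.DOWN
                edges.append(DysregulationEdge(c, m, d))
    return SignedBipartiteNetwork(cancers, mirnas, edges)
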