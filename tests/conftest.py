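import numpy as np
import pytest

from mirflow import (
    AssociationTable,
    GeneSetCollection,
    ModelParams,
    SimilarityMatrix,
    assemble_network,
    generate_benchmark,
)

EMPTY_SETS = GeneSetCollection(sets={})


@pytest.fixture(scope="session")
def bench():
    """The default planted benchmark (seed 1)."""
    return generate_benchmark()


@pytest.fixture()
def tiny_network():
    """Two miRNAs (sim 0.5), two diseases (sim 0.5), two associations.

    With alpha = beta = 0.4 and gamma = 1 this yields a 4-node, 4-edge
    network whose max flows are small enough to verify by hand.
    """
    mirna_sim = SimilarityMatrix(["m1", "m2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    disease_sim = SimilarityMatrix(["d1", "d2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    assoc = AssociationTable.from_pairs([("m1", "d1"), ("m2", "d2")])
    params = ModelParams(alpha=0.4, beta=0.4, gamma=1.0, eta=0.0, sigma=0.0)
    network = assemble_network(
        mirna_sim, disease_sim, assoc, EMPTY_SETS, EMPTY_SETS, params
    )
    return network, params


def brute_force_min_cut(arcs, source, sink):
    """Exhaustive min-cut over all source/sink partitions (oracle)."""
    nodes = sorted({n for arc in arcs for n in arc} | {source, sink})
    others = [n for n in nodes if n not in (source, sink)]
    best = None
    for mask in range(1 << len(others)):
        side = {source} | {o for i, o in enumerate(others) if mask >> i & 1}
        cut = sum(c for (u, v), c in arcs.items() if u in side and v not in side)
        best = cut if best is None else min(best, cut)
    return best
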