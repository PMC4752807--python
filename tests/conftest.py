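import itertools

import numpy as np
import pytest

from netdim import BinaryGraph


@pytest.fixture
def p4():
    """Path 0-1-2-3."""
    return BinaryGraph.from_edges([(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def c5():
    return BinaryGraph.from_edges([(i, (i + 1) % 5) for i in range(5)])


@pytest.fixture
def c4():
    return BinaryGraph.from_edges([(i, (i + 1) % 4) for i in range(4)])


def complete_graph(n: int) -> BinaryGraph:
    return BinaryGraph((1 - np.eye(n)).astype(np.uint8))


def random_graph(n: int, p: float, seed: int) -> BinaryGraph:
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=np.uint8)
    iu = np.triu_indices(n, k=1)
    keep = rng.random(iu[0].size) < p
    A[iu[0][keep], iu[1][keep]] = 1
    A |= A.T
    return BinaryGraph(A)


def random_tree(n: int, seed: int) -> BinaryGraph:
    rng = np.random.default_rng(seed)
    edges = [(int(rng.integers(0, v)), v) for v in range(1, n)]
    return BinaryGraph.from_edges(edges, nodes=range(n))


def brute_force_max_clique(g: BinaryGraph) -> int:
    """Exhaustive maximum-clique cardinality, for n small enough to enumerate."""
    n = g.n
    A = g.adjacency.toarray()
    best = 1
    for size in range(n, 0, -1):
        if size <= best:
            break
        for subset in itertools.combinations(range(n), size):
            if all(A[u, v] for u, v in itertools.combinations(subset, 2)):
                best = size
                break
        if best == size:
            break
    return best


def brute_force_all_max_cliques(g: BinaryGraph) -> set[frozenset]:
    n = g.n
    A = g.adjacency.toarray()
    best = brute_force_max_clique(g)
    out = set()
    for subset in itertools.combinations(range(n), best):
        if all(A[u, v] for u, v in itertools.combinations(subset, 2)):
            out.add(frozenset(subset))
    return out
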