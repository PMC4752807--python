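"""Validation-graph generators.

``lattice_graph`` builds the 1D/2D grids whose topological dimension a
dimension measure must recover.  ``fractal_model`` builds the
hub-repulsion family f(g, n, m, e): starting from a single node, each
generation multiplies the node count by ``n_factor`` and the node degree
by ``m_factor``, while the parameter ``e`` interpolates between maximal
hub repulsion (e = 0: every inherited edge is subdivided, distances grow
by ``m_factor`` per generation, the graph is a fractal with limiting
dimension ln(n_factor)/ln(m_factor)) and full hub attraction (e = 1:
inherited edges stay direct links, diameters stay small and the graph is
a small world).  ``add_random_edges`` injects the noise that drives the
fractal-to-small-world transition.  ``synthetic_correlation_matrix``
emulates the block structure of region-of-interest |correlation|
matrices from resting-state fMRI so the weighted pipelines can be
exercised without any imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netdim.graph_core import BinaryGraph, WeightedGraph

__all__ = [
    "ModelSpec",
    "lattice_graph",
    "fractal_model",
    "add_random_edges",
    "synthetic_correlation_matrix",
]


@dataclass(frozen=True)
class ModelSpec:
    """Parameters of the hub-repulsion model family f(g, n, m, e)."""

    g: int
    n_factor: int = 4
    m_factor: int = 2
    e: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.n_factor < 2 or self.m_factor < 2:
            raise ValueError("n_factor and m_factor must be >= 2")
        if not 0.0 <= self.e <= 1.0:
            raise ValueError("e must lie in [0, 1]")


def lattice_graph(dims: list[int]) -> BinaryGraph:
    """1D path or 2D four-neighbour grid (no wraparound).

    ``dims`` holds one or two extents, each >= 2.  Node labels are the
    integer position (1D) or ``(row, col)`` tuples (2D).
    """
    if not 1 <= len(dims) <= 2:
        raise ValueError("only 1- and 2-dimensional lattices are supported")
    if any(d < 2 for d in dims):
        raise ValueError("extents must be >= 2")
    if len(dims) == 1:
        n = dims[0]
        return BinaryGraph.from_edges([(i, i + 1) for i in range(n - 1)])
    rows, cols = dims
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append(((r, c), (r, c + 1)))
            if r + 1 < rows:
                edges.append(((r, c), (r + 1, c)))
    return BinaryGraph.from_edges(edges)


def fractal_model(spec: ModelSpec) -> BinaryGraph:
    """Generate f(g, n, m, e) by inverting a renormalisation process.

    Generation rule (one step, G_t -> G_{t+1}):

    1. every edge of G_t is, with probability ``e``, kept as a direct
       link (hub attraction); otherwise it is subdivided into a path of
       ``m_factor`` unit edges through ``m_factor - 1`` new way-point
       nodes (hub repulsion — inherited distances grow by ``m_factor``);
    2. every node v of G_t receives ``(m_factor - 1) * deg_t(v)`` new
       leaf offspring, multiplying its degree by ``m_factor`` (the
       isolated start node counts deg = 1);
    3. leaf offspring are added to (or removed from) uniformly random
       nodes until the size is exactly ``n_factor * |V(G_t)|``.

    The result always has exactly ``n_factor ** g`` nodes.  Way-points
    are never touched by the budget adjustment, so the distance scaling
    that makes e = 0 fractal is preserved.
    """
    rng = np.random.default_rng(spec.seed)
    n_nodes = 1
    edges: list[tuple[int, int]] = []
    degree = {0: 0}
    for _ in range(spec.g):
        old_nodes = n_nodes
        old_edges = edges
        old_degree = degree
        new_edges: list[tuple[int, int]] = []
        nxt = old_nodes  # next free node id

        # (1) subdivide or keep every inherited edge
        for (u, v) in old_edges:
            if spec.e > 0 and rng.random() < spec.e:
                new_edges.append((u, v))
            else:
                prev = u
                for _ in range(spec.m_factor - 1):
                    new_edges.append((prev, nxt))
                    prev = nxt
                    nxt += 1
                new_edges.append((prev, v))

        # (2) leaf offspring proportional to the old degree
        removable: list[int] = []  # leaves, eligible for budget removal
        for v in range(old_nodes):
            d = old_degree[v] if old_degree[v] > 0 else 1
            for _ in range((spec.m_factor - 1) * d):
                new_edges.append((v, nxt))
                removable.append(nxt)
                nxt += 1

        # (3) adjust to the exact size budget with random leaves
        target = spec.n_factor * old_nodes
        if nxt < target:
            hosts = rng.integers(0, nxt, size=target - nxt)
            for h in hosts:
                new_edges.append((int(h), nxt))
                removable.append(nxt)
                nxt += 1
        elif nxt > target:
            surplus = nxt - target
            deg_now: dict[int, int] = {}
            for a, b in new_edges:
                deg_now[a] = deg_now.get(a, 0) + 1
                deg_now[b] = deg_now.get(b, 0) + 1
            droppable = [v for v in removable if deg_now.get(v, 0) == 1]
            if surplus > len(droppable):
                raise ValueError(
                    "n_factor too small for the requested degree growth: "
                    "cannot reach the size budget by removing leaves only"
                )
            drop = set(
                int(i) for i in rng.choice(np.array(droppable), size=surplus, replace=False)
            )
            new_edges = [e for e in new_edges if e[0] not in drop and e[1] not in drop]
            # compact node ids so they stay 0..target-1
            remap: dict[int, int] = {}
            for e in new_edges:
                for x in e:
                    if x not in remap:
                        remap[x] = len(remap)
            for v in range(nxt):
                if v not in drop and v not in remap:
                    remap[v] = len(remap)
            new_edges = [(remap[a], remap[b]) for a, b in new_edges]
            nxt = target

        n_nodes = target
        edges = new_edges
        degree = {v: 0 for v in range(n_nodes)}
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1

    if n_nodes == 1:
        import scipy.sparse as sp

        return BinaryGraph(sp.csr_matrix((1, 1), dtype=np.uint8))
    return BinaryGraph.from_edges(edges, nodes=range(n_nodes))


def add_random_edges(g: BinaryGraph, fraction: float, seed: int = 0) -> BinaryGraph:
    """Add ``round(fraction * E)`` uniformly random new edges.

    The original edges are untouched; new edges are drawn without
    replacement from the vacant non-loop pairs.
    """
    if fraction < 0:
        raise ValueError("fraction must be nonnegative")
    n_new = int(round(fraction * g.edge_count))
    if n_new == 0:
        return BinaryGraph(g.adjacency, labels=g.labels)
    rng = np.random.default_rng(seed)
    existing = {tuple(sorted(e)) for e in _index_edges(g)}
    vacant_total = g.n * (g.n - 1) // 2 - len(existing)
    if n_new > vacant_total:
        raise ValueError(f"requested {n_new} new edges but only {vacant_total} vacant pairs")
    new: set[tuple[int, int]] = set()
    while len(new) < n_new:
        i, j = rng.integers(0, g.n, size=2)
        if i == j:
            continue
        pair = (int(min(i, j)), int(max(i, j)))
        if pair in existing or pair in new:
            continue
        new.add(pair)
    A = g.adjacency.tolil(copy=True)
    for i, j in new:
        A[i, j] = 1
        A[j, i] = 1
    return BinaryGraph(A.tocsr(), labels=g.labels)


def _index_edges(g: BinaryGraph) -> list[tuple[int, int]]:
    import scipy.sparse as sp

    coo = sp.triu(g.adjacency, k=1).tocoo()
    return list(zip(coo.row.tolist(), coo.col.tolist()))


def synthetic_correlation_matrix(
    n_nodes: int,
    block_sizes: list[int],
    within_weight: float = 0.8,
    between_weight: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> WeightedGraph:
    """Block-structured stand-in for an fMRI |correlation| matrix.

    ``block_sizes`` must partition ``n_nodes``; within-block entries get
    ``within_weight``, between-block entries ``between_weight``, then
    symmetric Gaussian noise of standard deviation ``noise_sd`` is added
    and the matrix is clipped to [0, 1] (absolute correlations).  The
    diagonal stays zero.
    """
    if sum(block_sizes) != n_nodes or any(b < 1 for b in block_sizes):
        raise ValueError("block_sizes must partition the node set")
    if not (0 <= between_weight <= 1 and 0 <= within_weight <= 1):
        raise ValueError("weights must lie in [0, 1]")
    membership = np.repeat(np.arange(len(block_sizes)), block_sizes)
    same = membership[:, None] == membership[None, :]
    W = np.where(same, within_weight, between_weight).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=(n_nodes, n_nodes))
        noise = (noise + noise.T) / 2.0
        W = W + noise
    W = np.clip(W, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W)
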