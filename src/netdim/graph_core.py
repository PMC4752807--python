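"""Graph containers, shortest-path machinery and elementary topological measures.

Three containers are used throughout the package:

``BinaryGraph``
    A simple undirected graph (no self loops, no multi-edges).  This is
    the object the Ndim complexity dimension is defined on.

``WeightedGraph``
    A symmetric nonnegative weight matrix with zero diagonal, interpreted
    with communication-network semantics: a *larger* weight means the two
    nodes are functionally *closer* (e.g. absolute correlation of fMRI
    time series between two regions of interest).

``IntegerLengthGraph``
    A graph whose edges carry positive integer lengths; a length of 0
    encodes "no edge".  This is the approximating multigraph produced by
    the functional-distance route to Ndim.

All distance computations go through :func:`shortest_path_matrix`, which
uses breadth-first search for binary graphs and Dijkstra for integer
lengths (via ``scipy.sparse.csgraph``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

__all__ = [
    "BinaryGraph",
    "WeightedGraph",
    "IntegerLengthGraph",
    "DistanceSummary",
    "shortest_path_matrix",
    "connected_components",
    "power_graph",
    "cost",
    "global_efficiency",
]


def _validate_labels(labels: Sequence[Hashable] | None, n: int) -> tuple:
    if labels is None:
        return tuple(range(n))
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} nodes")
    if len(set(labels)) != n:
        raise ValueError("node labels must be unique")
    return labels


class BinaryGraph:
    """Undirected simple graph over ``n`` labelled nodes.

    Parameters
    ----------
    adjacency
        Square 0/1 matrix (dense or sparse).  Must be symmetric with a
        zero diagonal.
    labels
        Optional node labels; defaults to ``0..n-1``.
    """

    def __init__(self, adjacency, labels: Sequence[Hashable] | None = None):
        A = sp.csr_matrix(adjacency, dtype=np.uint8)
        if A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        A.setdiag(0)
        A.eliminate_zeros()
        data = A.data
        if data.size and not np.all(data == 1):
            raise ValueError("adjacency entries must be 0 or 1")
        if (A != A.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        A.sort_indices()
        self._adj = A
        self.labels = _validate_labels(labels, A.shape[0])
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Hashable, Hashable]],
        nodes: Sequence[Hashable] | None = None,
    ) -> "BinaryGraph":
        """Build a graph from an iterable of (u, v) label pairs.

        Isolated nodes can be supplied through ``nodes``; the node order
        is the order of first appearance (``nodes`` first, then edges).
        """
        order: dict[Hashable, int] = {}
        if nodes is not None:
            for u in nodes:
                order.setdefault(u, len(order))
        pairs = []
        for u, v in edges:
            if u == v:
                raise ValueError(f"self loop at {u!r}")
            order.setdefault(u, len(order))
            order.setdefault(v, len(order))
            pairs.append((order[u], order[v]))
        n = len(order)
        if n == 0:
            raise ValueError("empty graph")
        rows = np.array([p[0] for p in pairs] + [p[1] for p in pairs], dtype=np.int64)
        cols = np.array([p[1] for p in pairs] + [p[0] for p in pairs], dtype=np.int64)
        A = sp.coo_matrix((np.ones(rows.size, dtype=np.uint8), (rows, cols)), shape=(n, n))
        A = A.tocsr()
        A.data = np.minimum(A.data, 1).astype(np.uint8)
        return cls(A, labels=list(order))

    @classmethod
    def from_networkx(cls, G) -> "BinaryGraph":
        import networkx as nx

        nodes = list(G.nodes())
        A = nx.to_scipy_sparse_array(G, nodelist=nodes, dtype=np.uint8)
        return cls(A, labels=nodes)

    # -- basic accessors ------------------------------------------------
    @property
    def n(self) -> int:
        return self._adj.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self._adj.nnz // 2)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 CSR adjacency (read-only by convention)."""
        return self._adj

    def degrees(self) -> np.ndarray:
        return np.asarray(self._adj.sum(axis=1)).ravel().astype(np.int64)

    def neighbors(self, i: int) -> np.ndarray:
        return self._adj.indices[self._adj.indptr[i] : self._adj.indptr[i + 1]]

    def index_of(self, label: Hashable) -> int:
        return self._index[label]

    def subgraph(self, indices: Sequence[int]) -> "BinaryGraph":
        """Induced subgraph on the given node *indices* (labels kept)."""
        idx = np.asarray(indices, dtype=np.int64)
        A = self._adj[idx][:, idx]
        return BinaryGraph(A, labels=[self.labels[i] for i in idx])

    def edges(self) -> list[tuple[Hashable, Hashable]]:
        coo = sp.triu(self._adj, k=1).tocoo()
        return [(self.labels[i], self.labels[j]) for i, j in zip(coo.row, coo.col)]

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.labels)
        G.add_edges_from(self.edges())
        return G

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryGraph(n={self.n}, E={self.edge_count})"


class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    def __init__(self, weights, labels: Sequence[Hashable] | None = None):
        W = np.asarray(weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        if np.any(W < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(W, W.T, rtol=0.0, atol=1e-9):
            raise ValueError("weights must be symmetric")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        self.weights = W
        self.labels = _validate_labels(labels, W.shape[0])
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def max_weight(self) -> float:
        return float(self.weights.max()) if self.n else 0.0

    def support(self) -> BinaryGraph:
        """Binary graph of all strictly positive weights."""
        return BinaryGraph((self.weights > 0).astype(np.uint8), labels=self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"WeightedGraph(n={self.n})"


class IntegerLengthGraph:
    """Graph with positive integer edge lengths; 0 encodes absence."""

    def __init__(self, lengths, labels: Sequence[Hashable] | None = None):
        M = np.asarray(lengths)
        if not np.issubdtype(M.dtype, np.integer):
            Mf = np.asarray(lengths, dtype=float)
            if np.any(Mf != np.floor(Mf)):
                raise ValueError("edge lengths must be integers")
            M = Mf.astype(np.int64)
        else:
            M = M.astype(np.int64)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("lengths must be a square matrix")
        if np.any(M < 0):
            raise ValueError("edge lengths must be nonnegative")
        if not np.array_equal(M, M.T):
            raise ValueError("lengths must be symmetric")
        np.fill_diagonal(M, 0)
        self.lengths = M
        self.labels = _validate_labels(labels, M.shape[0])

    @property
    def n(self) -> int:
        return self.lengths.shape[0]

    def support(self) -> BinaryGraph:
        return BinaryGraph((self.lengths > 0).astype(np.uint8), labels=self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntegerLengthGraph(n={self.n})"


@dataclass
class DistanceSummary:
    """All-pairs shortest paths plus the scalar summaries Ndim needs.

    ``mu`` is the characteristic path length (normalised Wiener index):
    the mean of d(i, j) over distinct *reachable* pairs.  ``k`` is
    floor(mu); ``m_min`` the minimum positive distance (1 for binary
    graphs); ``diameter`` the largest finite distance.
    """

    dist: np.ndarray
    mu: float
    k: int
    m_min: float
    diameter: float
    connected: bool

    def __post_init__(self) -> None:
        self.dist.setflags(write=False)


def shortest_path_matrix(g: BinaryGraph | IntegerLengthGraph) -> DistanceSummary:
    """All-pairs shortest paths with the summaries mu, k, m_min, diameter.

    Binary graphs use hop counts (BFS); integer-length graphs use length
    sums (Dijkstra).  Unreachable pairs are reported as ``inf`` and mu is
    computed over reachable distinct pairs only; ``connected`` flags
    whether every pair was reachable.
    """
    if g.n < 1:
        raise ValueError("empty graph")
    if isinstance(g, IntegerLengthGraph):
        A = sp.csr_matrix(g.lengths.astype(float))
        dist = csgraph.dijkstra(A, directed=False)
    else:
        dist = csgraph.shortest_path(g.adjacency, method="D", directed=False, unweighted=True)
    return _summarize(dist)


def _summarize(dist: np.ndarray) -> DistanceSummary:
    n = dist.shape[0]
    iu = np.triu_indices(n, k=1)
    upper = dist[iu]
    finite = upper[np.isfinite(upper)]
    connected = finite.size == upper.size
    if finite.size == 0:
        mu = 0.0
        m_min = float("inf")
        diameter = 0.0
    else:
        mu = float(finite.mean())
        positive = finite[finite > 0]
        m_min = float(positive.min()) if positive.size else float("inf")
        diameter = float(finite.max())
    return DistanceSummary(
        dist=dist,
        mu=mu,
        k=int(np.floor(mu)),
        m_min=m_min,
        diameter=diameter,
        connected=connected,
    )


def connected_components(g: BinaryGraph | WeightedGraph | IntegerLengthGraph) -> list[np.ndarray]:
    """Partition of node indices into connected components.

    Ordered by decreasing size; ties broken by smallest member index.
    For weighted/length graphs, any strictly positive entry is an edge.
    """
    if isinstance(g, BinaryGraph):
        A = g.adjacency
    else:
        A = sp.csr_matrix((getattr(g, "weights", None) if isinstance(g, WeightedGraph) else g.lengths) > 0)
    ncomp, membership = csgraph.connected_components(A, directed=False)
    comps = [np.flatnonzero(membership == c) for c in range(ncomp)]
    comps.sort(key=lambda idx: (-idx.size, idx[0]))
    return comps


def power_graph(g: BinaryGraph, k: int, dist: np.ndarray | None = None) -> BinaryGraph:
    """The k-th graph power: edge (i, j) iff 0 < d(i, j) <= k in ``g``.

    A clique of the power graph is exactly a vertex set of ``g`` with
    pairwise distance <= k, i.e. a k-clique of ``g``.  The precomputed
    distance matrix may be passed to avoid recomputation.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist is None:
        dist = shortest_path_matrix(g).dist
    A = ((dist > 0) & (dist <= k)).astype(np.uint8)
    return BinaryGraph(A, labels=g.labels)


def cost(g: BinaryGraph) -> float:
    """Global normalised edge density E / (n(n-1)/2)."""
    if g.n < 2:
        raise ValueError("cost requires at least 2 nodes")
    return g.edge_count / (g.n * (g.n - 1) / 2)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/d(i, j) over distinct pairs, with 1/inf := 0."""
    if g.n < 2:
        raise ValueError("global efficiency requires at least 2 nodes")
    dist = shortest_path_matrix(g).dist
    iu = np.triu_indices(g.n, k=1)
    upper = dist[iu]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(upper) & (upper > 0), 1.0 / upper, 0.0)
    return float(inv.mean())
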