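"""Exact maximum-clique and maximum-k-clique search.

The solver is a branch-and-bound in the Carraghan–Pardalos / Tomita
tradition: vertices are ordered by descending degree, candidate sets are
kept as arbitrary-precision integer bitsets, and a greedy colouring of
the candidate set supplies the upper bound used for pruning (a clique
can contain at most one vertex per colour class).  Colouring bounds are
particularly effective on the dense graph powers produced by the Ndim
pipeline, whose complements are sparse.

Two further accelerations matter in practice:

* an initial incumbent from a greedy clique plus an optional caller
  supplied ``lower_bound`` (e.g. from the Ndim monotonicity rule,
  :func:`ndim_lower_bound`);
* peeling: a clique of size ``s`` needs every member to have degree at
  least ``s - 1``, so vertices of smaller degree are removed iteratively
  before the search starts.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass

import numpy as np

from netdim.graph_core import BinaryGraph, connected_components, power_graph

__all__ = [
    "CliqueResult",
    "max_clique",
    "all_maximum_cliques",
    "max_k_clique",
    "ndim_lower_bound",
    "CliqueEnumerationCap",
]

_MIN_RECURSION = 50_000
# above this many surviving vertices the twin-contracted numba engine takes over
_FAST_CUTOVER = 100


class CliqueEnumerationCap(RuntimeError):
    """Raised when clique enumeration exceeds its configured cap."""


@dataclass(frozen=True)
class CliqueResult:
    """A clique, its cardinality, and whether optimality was proven."""

    vertices: tuple
    cardinality: int
    exhausted: bool = True

    def __post_init__(self) -> None:
        if self.cardinality != len(self.vertices) or self.cardinality < 1:
            raise ValueError("cardinality must equal the number of vertices (>= 1)")


def _adjacency_bitsets(g: BinaryGraph) -> list[int]:
    """Row bitsets of the adjacency matrix as Python integers."""
    A = g.adjacency
    n = g.n
    masks = []
    row = np.zeros(n, dtype=bool)
    for i in range(n):
        row[:] = False
        row[A.indices[A.indptr[i] : A.indptr[i + 1]]] = True
        masks.append(int.from_bytes(np.packbits(row, bitorder="little").tobytes(), "little"))
    return masks


def _greedy_clique(masks: list[int], order: list[int], restarts: int = 8) -> list[int]:
    """A quick large clique to seed the incumbent (by-degree heuristic)."""
    best: list[int] = []
    for start in order[: max(1, restarts)]:
        clique = [start]
        P = masks[start]
        while P:
            # highest-degree remaining candidate (order is degree-descending)
            v = -1
            for u in order:
                if (P >> u) & 1:
                    v = u
                    break
            clique.append(v)
            P &= masks[v]
        if len(clique) > len(best):
            best = clique
    return best


def _peel(masks: list[int], alive: int, need: int) -> int:
    """Remove vertices that cannot belong to a clique of size ``need``."""
    changed = True
    while changed:
        changed = False
        P = alive
        while P:
            v = (P & -P).bit_length() - 1
            P &= P - 1
            if (masks[v] & alive).bit_count() < need - 1:
                alive ^= 1 << v
                changed = True
    return alive


class _Search:
    """Branch-and-bound state shared across the recursion."""

    def __init__(self, masks: list[int], best_size: int, node_budget: int | None = None):
        self.masks = masks
        self.best_size = best_size
        self.best: list[int] | None = None
        self.stack: list[int] = []
        self.remaining = -1 if node_budget is None else int(node_budget)
        self.exhausted = True

    def expand(self, P: int) -> None:
        masks = self.masks
        # greedy colouring of P; vertices listed colour-by-colour
        order: list[int] = []
        bound: list[int] = []
        uncoloured = P
        colour = 0
        while uncoloured:
            colour += 1
            Q = uncoloured
            while Q:
                v = (Q & -Q).bit_length() - 1
                bit = 1 << v
                Q &= ~masks[v]
                Q ^= bit
                uncoloured ^= bit
                order.append(v)
                bound.append(colour)
        depth = len(self.stack)
        for i in range(len(order) - 1, -1, -1):
            if not self.exhausted:
                return
            if depth + bound[i] <= self.best_size:
                return
            if self.remaining == 0:
                self.exhausted = False
                return
            if self.remaining > 0:
                self.remaining -= 1
            v = order[i]
            self.stack.append(v)
            if depth + 1 > self.best_size:
                self.best_size = depth + 1
                self.best = list(self.stack)
            newP = P & masks[v]
            if newP:
                self.expand(newP)
            self.stack.pop()
            P ^= 1 << v


def _fast_clique_search(
    g: BinaryGraph,
    alive: int,
    floor: int,
    node_budget: int | None,
) -> tuple[int, list[int], bool]:
    """Twin-contracted numba search among ``alive`` for a clique > ``floor``.

    Vertices with identical closed neighbourhoods (within ``alive``) are
    interchangeable — any maximum clique can be extended to a union of
    whole twin classes — so they collapse into single weighted vertices.
    Dense graph powers shrink a lot under this contraction.  Returns
    (best size, vertex indices, exhausted); the size equals ``floor``
    when nothing better was found.
    """
    from netdim import _fastclique

    A = g.adjacency.toarray().astype(bool)
    idx = [v for v in range(g.n) if (alive >> v) & 1]
    sub = A[np.ix_(idx, idx)]
    m0 = len(idx)
    closed = sub | np.eye(m0, dtype=bool)
    groups: dict[bytes, list[int]] = {}
    for j in range(m0):
        groups.setdefault(closed[j].tobytes(), []).append(j)
    classes = list(groups.values())
    reps = [c[0] for c in classes]
    weights = np.array([len(c) for c in classes], dtype=np.int64)
    CA = sub[np.ix_(reps, reps)]
    packed = _fastclique.pack_bitsets(CA)
    mask = np.zeros(packed.shape[1], dtype=np.uint64)
    for j in range(len(reps)):
        mask[j >> 6] |= np.uint64(1) << np.uint64(j & 63)
    budget = -1 if node_budget is None else int(node_budget)
    bw, members, exhausted = _fastclique.weighted_clique_solve(
        packed, weights, mask, int(floor), budget
    )
    verts: list[int] = []
    if bw > floor:
        for j in np.flatnonzero(members):
            verts.extend(idx[u] for u in classes[j])
    return int(bw), verts, bool(exhausted)


def max_clique(
    g: BinaryGraph,
    lower_bound: int | None = None,
    initial: list[int] | None = None,
    node_budget: int | None = None,
) -> CliqueResult | None:
    """Maximum clique of ``g`` (exact unless a ``node_budget`` truncates).

    If ``lower_bound`` is given, the search only looks for cliques of at
    least that cardinality; ``None`` is returned when no such clique
    exists.  A valid lower bound never changes the reported cardinality,
    only the runtime.  ``initial`` may supply a known clique (node
    indices) as the starting incumbent.  ``node_budget`` caps the number
    of branch expansions: if the cap is hit, the best clique found so
    far is returned with ``exhausted=False`` — a certified lower bound.
    The search is deterministic for a fixed input, including truncation.

    Large instances (or any budgeted search with numba available) run on
    the twin-contracted numba engine in :mod:`netdim._fastclique`; small
    ones use the pure-Python reference search.  Both are the same
    branch-and-bound and return identical cardinalities.
    """
    if g.n == 0:
        raise ValueError("empty graph")
    if lower_bound is not None:
        if lower_bound > g.n:
            raise ValueError(f"lower_bound {lower_bound} exceeds node count {g.n}")
        lower_bound = max(int(lower_bound), 1)

    masks = _adjacency_bitsets(g)
    deg = g.degrees()
    order = sorted(range(g.n), key=lambda v: (-deg[v], v))

    sys.setrecursionlimit(max(sys.getrecursionlimit(), _MIN_RECURSION))

    incumbent = _greedy_clique(masks, order)
    if initial is not None:
        initial = [int(v) for v in initial]
        for i, u in enumerate(initial):
            for v in initial[i + 1 :]:
                if not (masks[u] >> v) & 1:
                    raise ValueError("initial is not a clique")
        if len(initial) > len(incumbent):
            incumbent = initial
    best_size = len(incumbent)
    floor = 0 if lower_bound is None else lower_bound - 1
    start = max(best_size, floor)
    if best_size <= floor:
        incumbent = []  # incumbent did not reach the requested bound

    alive = _peel(masks, (1 << g.n) - 1, start + 1)
    exhausted = True
    best: list[int] = incumbent
    if alive:
        from netdim._fastclique import HAVE_NUMBA

        if HAVE_NUMBA and (alive.bit_count() > _FAST_CUTOVER or node_budget is not None):
            size, verts, exhausted = _fast_clique_search(g, alive, start, node_budget)
            if size > start:
                best = verts
        else:
            pruned = [masks[v] & alive for v in range(g.n)]
            search = _Search(pruned, start, node_budget=node_budget)
            search.expand(alive)
            exhausted = search.exhausted
            if search.best is not None:
                best = search.best

    if not best:
        if not exhausted:
            raise RuntimeError(
                "node budget exhausted before any clique reached the lower bound; "
                "raise the budget or drop the lower bound"
            )
        return None  # lower_bound given and proven unmet
    verts_out = tuple(g.labels[v] for v in sorted(best))
    return CliqueResult(vertices=verts_out, cardinality=len(best), exhausted=exhausted)


def _best_ball_k_clique(g: BinaryGraph, k: int, dist: np.ndarray) -> list[int]:
    """Largest ball-shaped k-clique: a valid k-clique in *any* graph.

    All nodes within distance floor(k/2) of a common centre are pairwise
    within distance k; for odd k the same holds for nodes within
    (k-1)/2 of either endpoint of an edge.  On trees these balls are not
    just feasible but optimal: a vertex set of diameter <= k always fits
    inside the ball around the (node or edge) centre of its diametral
    path.
    """
    r = k // 2
    within = dist <= r
    node_counts = within.sum(axis=1)
    best_v = int(np.argmax(node_counts))
    members = np.flatnonzero(within[best_v])
    best = members.tolist()
    if k % 2 == 1:
        A = g.adjacency
        coo = A.tocoo()
        sel = coo.row < coo.col
        rows, cols = coo.row[sel], coo.col[sel]
        near = dist <= r  # r == (k-1)/2 here
        sizes = (near[rows] | near[cols]).sum(axis=1)
        i = int(np.argmax(sizes))
        if sizes[i] > len(best):
            best = np.flatnonzero(near[rows[i]] | near[cols[i]]).tolist()
    return best


def solve_max_k_clique(
    g: BinaryGraph,
    k: int,
    dist: np.ndarray,
    lower_bound: int | None = None,
    node_budget: int | None = None,
) -> CliqueResult | None:
    """Maximum k-clique of a connected graph given its distance matrix.

    Trees are solved exactly by ball enumeration (see
    :func:`_best_ball_k_clique`); for every other graph the best ball
    seeds the branch-and-bound on the k-th power as a strong incumbent.
    ``node_budget`` truncates that search deterministically (result
    flagged ``exhausted=False``, a certified lower bound).
    """
    ball = _best_ball_k_clique(g, k, dist)
    if g.edge_count == g.n - 1:  # connected + n-1 edges: a tree, ball is optimal
        if lower_bound is not None and len(ball) < lower_bound:
            return None
        verts = tuple(g.labels[v] for v in sorted(ball))
        return CliqueResult(vertices=verts, cardinality=len(ball), exhausted=True)
    pg = power_graph(g, k, dist=dist)
    return max_clique(pg, lower_bound=lower_bound, initial=ball, node_budget=node_budget)


class _EnumSearch:
    """Collect every clique of exactly the target cardinality."""

    def __init__(self, masks: list[int], target: int, cap: int):
        self.masks = masks
        self.target = target
        self.cap = cap
        self.found: list[tuple[int, ...]] = []
        self.stack: list[int] = []

    def expand(self, P: int) -> None:
        masks = self.masks
        depth = len(self.stack)
        if depth == self.target:
            if len(self.found) >= self.cap:
                raise CliqueEnumerationCap(f"more than {self.cap} maximum cliques")
            self.found.append(tuple(sorted(self.stack)))
            return
        order: list[int] = []
        bound: list[int] = []
        uncoloured = P
        colour = 0
        while uncoloured:
            colour += 1
            Q = uncoloured
            while Q:
                v = (Q & -Q).bit_length() - 1
                bit = 1 << v
                Q &= ~masks[v]
                Q ^= bit
                uncoloured ^= bit
                order.append(v)
                bound.append(colour)
        for i in range(len(order) - 1, -1, -1):
            if depth + bound[i] < self.target:
                return
            v = order[i]
            self.stack.append(v)
            newP = P & masks[v]
            if newP or depth + 1 == self.target:
                self.expand(newP)
            self.stack.pop()
            P ^= 1 << v


def all_maximum_cliques(g: BinaryGraph, cap: int = 10**6) -> list[CliqueResult]:
    """Every maximum clique of ``g``, in sorted-vertex lexicographic order.

    The enumeration prunes branches that cannot reach the (precomputed)
    maximum cardinality; ``cap`` guards pathological inputs, raising
    :class:`CliqueEnumerationCap` when exceeded.
    """
    top = max_clique(g)
    assert top is not None
    masks = _adjacency_bitsets(g)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), _MIN_RECURSION))
    search = _EnumSearch(masks, top.cardinality, cap)
    search.expand((1 << g.n) - 1)
    cliques = sorted(set(search.found))
    return [
        CliqueResult(vertices=tuple(g.labels[v] for v in c), cardinality=top.cardinality)
        for c in cliques
    ]


def max_k_clique(
    g: BinaryGraph,
    k: int,
    lower_bound: int | None = None,
    dist: np.ndarray | None = None,
    node_budget: int | None = None,
) -> CliqueResult | None:
    """Maximum k-clique: largest vertex set pairwise within distance k.

    Equivalent to a maximum clique of the k-th graph power.  The graph
    must be connected; apply per component otherwise.  A precomputed
    distance matrix may be passed to skip the all-pairs search;
    ``node_budget`` truncates the search deterministically (result
    flagged ``exhausted=False``).
    """
    if len(connected_components(g)) > 1:
        raise ValueError("graph is disconnected; compute per connected component")
    if k < 1:
        raise ValueError("k must be >= 1")
    if dist is None:
        from netdim.graph_core import shortest_path_matrix

        dist = shortest_path_matrix(g).dist
    return solve_max_k_clique(g, k, dist, lower_bound=lower_bound, node_budget=node_budget)


def ndim_lower_bound(prev_ndim: float, k_now: int) -> int:
    """Monotonicity-based seed for the clique search on a grown graph.

    A graph that contains a subgraph of complexity ``prev_ndim`` must,
    for its current ``k``, contain a k-clique of at least
    ``floor(exp(prev_ndim * log(k_now + 1)))`` vertices.  Flooring keeps
    the bound always valid.
    """
    if prev_ndim < 0:
        raise ValueError("prev_ndim must be nonnegative")
    if k_now < 1:
        raise ValueError("k_now must be >= 1")
    # tiny epsilon so exact integer powers survive float round-off
    return int(math.floor(math.exp(prev_ndim * math.log(k_now + 1)) + 1e-9))
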