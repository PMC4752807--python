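"""Numba-accelerated weighted maximum-clique search.

This is the high-throughput engine behind :func:`netdim.clique.max_clique`
for large instances.  The algorithm is the same branch-and-bound as the
pure-Python reference implementation in :mod:`netdim.clique` (Tomita-style
greedy-colouring bound), generalised to integer vertex weights so that it
can run on twin-contracted graphs: vertices with identical closed
neighbourhoods are interchangeable, so they collapse into one weighted
vertex, which shrinks dense graph powers considerably.

The module degrades gracefully: if numba is unavailable the caller falls
back to the pure-Python search, so the package has no hard dependency on
a JIT compiler.  Results are deterministic and exact either way.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by which path the tests take
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]

__all__ = ["HAVE_NUMBA", "pack_bitsets", "weighted_clique_solve"]

_ONE = np.uint64(1)
_ZERO = np.uint64(0)
_SIX = np.uint64(6)
_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_F56 = np.uint64(56)


def pack_bitsets(rows: np.ndarray) -> np.ndarray:
    """Pack a boolean (n, n) adjacency matrix into (n, ceil(n/64)) uint64."""
    n = rows.shape[0]
    words = (n + 63) // 64
    packed = np.zeros((n, words), dtype=np.uint64)
    bits = np.packbits(rows, axis=1, bitorder="little")
    pad = words * 8 - bits.shape[1]
    if pad:
        bits = np.pad(bits, ((0, 0), (0, pad)))
    packed[:] = bits.view(np.uint64)
    return packed


@njit(cache=True)
def _popcount_row(row):
    total = 0
    for j in range(row.shape[0]):
        x = row[j]
        x = x - ((x >> _ONE) & _M1)
        x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
        x = (x + (x >> np.uint64(4))) & _M4
        total += int((x * _H01) >> _F56)
    return total


@njit(cache=True)
def _first_bit(row):
    """Index of lowest set bit, or -1 when empty."""
    for j in range(row.shape[0]):
        x = row[j]
        if x != _ZERO:
            b = 0
            while (x >> np.uint64(b)) & _ONE == _ZERO:
                b += 1
            return j * 64 + b
    return -1


@njit(cache=True)
def weighted_clique_solve(adj, w, alive, best_floor, max_nodes=-1):
    """Max-weight clique among ``alive`` with weight > ``best_floor``.

    ``adj``: (n, words) uint64 open-neighbourhood bitsets; ``w``: int64
    weights; ``alive``: (words,) uint64 candidate mask.  Returns
    ``(best_weight, membership, exhausted)`` where ``membership`` is an
    int8 vector; ``best_weight`` equals ``best_floor`` when nothing
    better was found.  Iterative Tomita-style branch and bound with a
    cumulative per-colour max-weight bound.

    ``max_nodes`` < 0 runs to completion (exact); otherwise the search
    stops after that many branch expansions and reports the incumbent
    with ``exhausted = False`` — a certified lower bound.  The node
    budget (rather than wall time) keeps truncated results deterministic
    across machines.
    """
    n = adj.shape[0]
    words = adj.shape[1]
    best = best_floor
    best_set = np.zeros(n, dtype=np.int8)
    nodes = 0
    exhausted = True

    P = np.zeros((n + 2, words), dtype=np.uint64)
    cur = np.zeros(n + 2, dtype=np.int64)
    idx = np.zeros(n + 2, dtype=np.int64)
    cnt = np.zeros(n + 2, dtype=np.int64)
    chosen = np.zeros(n + 2, dtype=np.int64)
    order = np.zeros((n + 2, n), dtype=np.int32)
    bound = np.zeros((n + 2, n), dtype=np.int64)

    scratch_unc = np.zeros(words, dtype=np.uint64)
    scratch_q = np.zeros(words, dtype=np.uint64)

    P[0, :] = alive
    cur[0] = 0
    level = 0
    fresh = True  # does P[level] still need colouring?
    while level >= 0:
        if fresh:
            # greedy colouring of P[level]; vertices appended colour by colour,
            # bound[i] = cumulative sum of per-colour max weights through colour(i)
            for j in range(words):
                scratch_unc[j] = P[level, j]
            c = 0
            accum = 0
            while True:
                v0 = _first_bit(scratch_unc)
                if v0 < 0:
                    break
                for j in range(words):
                    scratch_q[j] = scratch_unc[j]
                mx = 0
                start = c
                while True:
                    v = _first_bit(scratch_q)
                    if v < 0:
                        break
                    wv = np.uint64(v >> 6)
                    bv = _ONE << np.uint64(v & 63)
                    scratch_q[wv] &= ~bv
                    scratch_unc[wv] &= ~bv
                    for j in range(words):
                        scratch_q[j] &= ~adj[v, j]
                    order[level, c] = v
                    c += 1
                    if w[v] > mx:
                        mx = w[v]
                accum += mx
                for i in range(start, c):
                    bound[level, i] = accum
            cnt[level] = c
            idx[level] = c - 1
            fresh = False
            continue
        i = idx[level]
        if i < 0:
            level -= 1
            continue
        if cur[level] + bound[level, i] <= best:
            idx[level] = -1  # bounds only shrink leftwards: prune whole level
            continue
        nodes += 1
        if max_nodes >= 0 and nodes > max_nodes:
            exhausted = False
            break
        v = order[level, i]
        idx[level] = i - 1
        wv = np.uint64(v >> 6)
        bv = _ONE << np.uint64(v & 63)
        nonempty = False
        for j in range(words):
            x = P[level, j] & adj[v, j]
            P[level + 1, j] = x
            if x != _ZERO:
                nonempty = True
        P[level, wv] &= ~bv
        chosen[level] = v
        nc = cur[level] + w[v]
        if nc > best:
            best = nc
            for u in range(n):
                best_set[u] = 0
            for l in range(level):
                best_set[chosen[l]] = 1
            best_set[v] = 1
        if nonempty:
            cur[level + 1] = nc
            level += 1
            fresh = True
    return best, best_set, exhausted
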