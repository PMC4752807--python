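"""The Ndim complexity dimension for binary graphs.

For a connected binary graph G:

1. compute the characteristic path length mu (mean shortest-path
   distance over distinct pairs);
2. reduce it to the integer k = floor(mu);
3. find a maximum k-clique — a largest vertex set pairwise within
   distance k;
4. Ndim(G) = log |max k-clique| / log(k + 1).

The +1 in the denominator follows the box-size convention of the
box-covering literature.  On a complete graph mu = 1, k = 1 and the
whole vertex set is the clique, so Ndim(K_n) = log n / log 2 — the
maximum over all connected graphs of that size.  For d-dimensional grid
graphs Ndim approaches d as the grid grows, which is what qualifies it
as a dimension.

Disconnected graphs are handled by :func:`ndim_components_weighted`,
which averages per-component values with weights proportional to
component size (small components excluded, weights renormalised).

The generalised formula log|clique| / log((floor(mu) + m)/m), with m the
minimum positive distance, covers integer-length graphs produced by the
functional-distance route; it reduces to the binary formula at m = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from netdim.clique import ndim_lower_bound, solve_max_k_clique
from netdim.graph_core import (
    BinaryGraph,
    connected_components,
    shortest_path_matrix,
)

__all__ = [
    "NdimResult",
    "ndim_binary",
    "ndim_components_weighted",
    "ndim_from_distance_data",
    "ndim_growth_sequence",
]


@dataclass
class NdimResult:
    """An Ndim value together with its provenance.

    For a single connected graph ``component_weights`` is ``None``; for
    a component-weighted average it lists (size, component Ndim, weight)
    per retained component, and the clique fields describe the largest
    retained component.
    """

    value: float
    mu: float
    k: int
    m_min: float
    clique_cardinality: int
    clique_vertices: tuple
    component_weights: list[tuple[int, float, float]] | None = None
    exhausted: bool = True


def ndim_from_distance_data(clique_cardinality: int, mu: float, m_min: float) -> float:
    """log(clique)/log((floor(mu)+m)/m); the binary formula at m = 1."""
    if clique_cardinality < 1:
        raise ValueError("clique cardinality must be >= 1")
    if m_min <= 0:
        raise ValueError("minimum positive distance must be > 0")
    k = math.floor(mu)
    return math.log(clique_cardinality) / math.log((k + m_min) / m_min)


def ndim_binary(
    g: BinaryGraph,
    k_mode: str = "floor_mu",
    lower_bound: int | None = None,
    node_budget: int | None = None,
) -> NdimResult:
    """Ndim of a connected binary graph.

    ``k_mode`` selects the distance scale: ``"floor_mu"`` (default) uses
    k = floor(mu); ``"half_diameter"`` uses k = floor(diameter / 2), a
    variant that is less robust when short-path edges are added at
    random.  ``lower_bound`` seeds the clique search (see
    :func:`netdim.clique.ndim_lower_bound`); it must be valid, i.e. a
    k-clique of that size must exist.

    ``node_budget`` caps the clique search deterministically.  When the
    cap is hit the result carries ``exhausted=False`` and ``value`` is a
    certified *lower bound* on Ndim (the reported clique is real, it is
    just not proven maximum).  Some dense small-world instances are
    genuinely out of reach for exact search; the budget makes that case
    explicit instead of unbounded.
    """
    if g.n < 2:
        raise ValueError("Ndim requires at least 2 nodes")
    summary = shortest_path_matrix(g)
    if not summary.connected:
        raise ValueError("graph is disconnected; use ndim_components_weighted")
    if k_mode == "floor_mu":
        k = summary.k
    elif k_mode == "half_diameter":
        k = int(summary.diameter // 2)
    else:
        raise ValueError(f"unknown k_mode {k_mode!r}")
    k = max(k, 1)  # mu >= 1 for n >= 2; guard the degenerate floor
    clique = solve_max_k_clique(g, k, summary.dist, lower_bound=lower_bound, node_budget=node_budget)
    if clique is None:
        raise ValueError(f"no k-clique of size >= {lower_bound}; the supplied lower bound is invalid")
    value = math.log(clique.cardinality) / math.log(k + 1)
    return NdimResult(
        value=value,
        mu=summary.mu,
        k=k,
        m_min=1.0,
        clique_cardinality=clique.cardinality,
        clique_vertices=clique.vertices,
        exhausted=clique.exhausted,
    )


def ndim_components_weighted(
    g: BinaryGraph,
    min_component_size: int = 5,
    k_mode: str = "floor_mu",
) -> NdimResult:
    """Size-weighted average of per-component Ndim values.

    Components smaller than ``min_component_size`` carry too little
    information and are excluded; the weights of the retained components
    (component size / n over retained sizes) are renormalised to sum to
    one.  A connected graph reproduces :func:`ndim_binary` exactly.
    """
    comps = connected_components(g)
    retained = [c for c in comps if c.size >= max(min_component_size, 2)]
    if not retained:
        raise ValueError("no informative components")
    total = sum(c.size for c in retained)
    entries: list[tuple[int, float, float]] = []
    best: NdimResult | None = None
    for c in retained:
        sub = ndim_binary(g.subgraph(c), k_mode=k_mode)
        weight = c.size / total
        entries.append((int(c.size), sub.value, weight))
        if best is None:
            best = sub  # components are ordered by decreasing size
    assert best is not None
    value = sum(w * v for _, v, w in entries)
    return NdimResult(
        value=value,
        mu=best.mu,
        k=best.k,
        m_min=1.0,
        clique_cardinality=best.clique_cardinality,
        clique_vertices=best.clique_vertices,
        component_weights=entries,
    )


def ndim_growth_sequence(
    graphs: list[BinaryGraph],
    k_mode: str = "floor_mu",
    use_lower_bound: bool = True,
) -> list[NdimResult]:
    """Ndim along a growing graph family, seeding each clique search.

    For families where each stage contains (a renormalised copy of) the
    previous one, monotonicity gives a valid clique lower bound
    ``floor(exp(Ndim_prev * log(k_now + 1)))``, which can cut the search
    drastically.  If a seeded search comes back empty (the containment
    assumption failed for this family), the stage is recomputed without
    the seed, so results are always exact.
    """
    results: list[NdimResult] = []
    prev_value: float | None = None
    for g in graphs:
        summary = shortest_path_matrix(g)
        if not summary.connected:
            raise ValueError("growth sequence stages must be connected")
        k = max(summary.k if k_mode == "floor_mu" else int(summary.diameter // 2), 1)
        lb = None
        if use_lower_bound and prev_value is not None:
            lb = min(ndim_lower_bound(prev_value, k), g.n)
        clique = solve_max_k_clique(g, k, summary.dist, lower_bound=lb)
        if clique is None:  # seed was too optimistic for this family
            clique = solve_max_k_clique(g, k, summary.dist)
            assert clique is not None
        value = math.log(clique.cardinality) / math.log(k + 1)
        results.append(
            NdimResult(
                value=value,
                mu=summary.mu,
                k=k,
                m_min=1.0,
                clique_cardinality=clique.cardinality,
                clique_vertices=clique.vertices,
            )
        )
        prev_value = value
    return results
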