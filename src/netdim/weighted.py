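"""Three routes from a weighted network to Ndim.

A weighted graph W (communication semantics: larger weight = closer,
e.g. |correlation|) does not directly admit the binary definition of
Ndim.  Three procedures bridge the gap:

1. **Thresholding** — keep an edge wherever w(i, j) > tau (or, to study
   the weak-edge backbone, wherever 0 < w(i, j) < tau), then apply the
   component-weighted binary Ndim.  Fast, but reduces every weight to a
   yes/no decision.

2. **Monte-Carlo ensemble** — normalise the weights to probabilities by
   the joint maximum over all networks being compared and draw an
   ensemble of binary random graphs, each potential edge included with
   probability w̃(i, j).  Ndim of the weighted graph becomes a
   *distribution* of complexities, which makes differences between two
   networks statistically testable.

3. **Functional distances** — map weights to functional distances
   w̃ = 1/w, scale and round to an integer-length multigraph
   M = floor(c·W̃), take shortest paths, build the binary distance graph
   (edge iff d(i, j) <= floor(mu)) and read off
   Ndim = log|max clique| / log((floor(mu)+m)/m) with m the minimum
   positive distance.  The scale factor c (with constant kappa) is
   chosen so that Ndim is exactly invariant under W -> lambda·W.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from netdim.clique import max_clique
from netdim.graph_core import (
    BinaryGraph,
    IntegerLengthGraph,
    WeightedGraph,
    connected_components,
    shortest_path_matrix,
)
from netdim.ndim import NdimResult, ndim_components_weighted, ndim_from_distance_data

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdSpec",
    "EnsembleSpec",
    "ScalingSpec",
    "NdimDistribution",
    "threshold_binarize",
    "threshold_weights",
    "ndim_thresholded",
    "mc_sample",
    "mc_ndim_distribution",
    "functional_distance_transform",
    "multigraph_scale",
    "distance_graph",
    "ndim_functional",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Cut-off tau > 0 with mode 'above' (w > tau) or 'below' (0 < w < tau)."""

    tau: float
    mode: str = "above"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.mode not in ("above", "below"):
            raise ValueError("mode must be 'above' or 'below'")


@dataclass(frozen=True)
class EnsembleSpec:
    """Monte-Carlo ensemble parameters.

    ``joint_max`` is the normalisation constant: the maximum weight over
    *all* networks involved in a comparison, so that ensembles of
    different networks live on a common probability scale.
    """

    n_samples: int = 1000
    seed: int = 0
    joint_max: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.joint_max <= 0:
            raise ValueError("joint_max must be > 0")


@dataclass(frozen=True)
class ScalingSpec:
    """Scale constant for the functional-distance multigraph.

    ``kappa`` is the numerator constant of the scale factor
    c = kappa / (max finite w̃  -  min positive w̃); it must be large
    compared to (max/min - 1) so that rounding to integer lengths keeps
    every present edge at length >= 1.
    """

    kappa: float = 100.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class NdimDistribution:
    """Per-draw Ndim values of a Monte-Carlo ensemble plus metadata."""

    samples: np.ndarray
    seed: int
    n_samples: int
    k_per_draw: np.ndarray | None = None
    multiplicity_per_draw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size != self.n_samples:
            raise ValueError("sample count mismatch")


# ---------------------------------------------------------------------------
# 1. thresholding


def threshold_binarize(w: WeightedGraph, spec: ThresholdSpec) -> BinaryGraph:
    """Binary graph of the supra- (or sub-) threshold weights.

    mode 'above': edge iff w(i, j) > tau; mode 'below': edge iff
    0 < w(i, j) < tau.  Zero weights never become edges and the diagonal
    stays empty.
    """
    W = w.weights
    if spec.mode == "above":
        A = W > spec.tau
    else:
        A = (W > 0) & (W < spec.tau)
    A = A.astype(np.uint8)
    np.fill_diagonal(A, 0)
    return BinaryGraph(A, labels=w.labels)


def threshold_weights(w: WeightedGraph, spec: ThresholdSpec) -> WeightedGraph:
    """Zero out the weights on the wrong side of tau, keeping the rest.

    This is the pre-thresholding used before Monte-Carlo sampling: the
    surviving weights keep their values instead of collapsing to 1.
    """
    W = w.weights.copy()
    if spec.mode == "above":
        W[W <= spec.tau] = 0.0
    else:
        W[W >= spec.tau] = 0.0
    return WeightedGraph(W, labels=w.labels)


def ndim_thresholded(
    w: WeightedGraph,
    spec: ThresholdSpec,
    min_component_size: int = 5,
) -> NdimResult:
    """Threshold to a binary graph, then component-weighted Ndim."""
    return ndim_components_weighted(threshold_binarize(w, spec), min_component_size)


# ---------------------------------------------------------------------------
# 2. Monte-Carlo ensemble


def _draw_rng(seed: int, draw_index: int) -> np.random.Generator:
    # counter-based substream: reproducible regardless of execution order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(draw_index,)))


def mc_sample(w: WeightedGraph, spec: EnsembleSpec, draw_index: int) -> BinaryGraph:
    """One binary random realisation of the normalised weighted graph.

    Each potential edge (i < j) receives a uniform p in (0, 1] and is
    included iff p <= w̃(i, j) = w(i, j)/joint_max, independently.  A
    weight of 0 therefore never yields an edge and a normalised weight
    of 1 always does.
    """
    wt = w.weights / spec.joint_max
    if wt.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError("not normalized: some weight exceeds joint_max")
    n = w.n
    rng = _draw_rng(spec.seed, draw_index)
    iu = np.triu_indices(n, k=1)
    p = 1.0 - rng.random(iu[0].size)  # uniform on (0, 1]
    keep = p <= wt[iu]
    A = np.zeros((n, n), dtype=np.uint8)
    A[iu[0][keep], iu[1][keep]] = 1
    A |= A.T
    return BinaryGraph(A, labels=w.labels)


def mc_ndim_distribution(
    w: WeightedGraph,
    spec: EnsembleSpec,
    pre_threshold: ThresholdSpec | None = None,
    min_component_size: int = 5,
    collect_metadata: bool = True,
) -> NdimDistribution:
    """Ndim distribution over an ensemble of binary random realisations.

    If ``pre_threshold`` is given the weights are first zeroed on the
    wrong side of tau (values on the right side are kept, not set to 1).
    Per draw the component-weighted Ndim is recorded; with
    ``collect_metadata`` the per-draw k and the number of distinct
    maximum k-cliques in the largest retained component are kept as
    well (the multiplicity enumeration roughly doubles the cost).
    """
    from netdim.clique import all_maximum_cliques
    from netdim.graph_core import power_graph

    if pre_threshold is not None:
        w = threshold_weights(w, pre_threshold)
    samples = np.empty(spec.n_samples)
    ks = np.zeros(spec.n_samples, dtype=np.int64) if collect_metadata else None
    mult = np.zeros(spec.n_samples, dtype=np.int64) if collect_metadata else None
    for d in range(spec.n_samples):
        b = mc_sample(w, spec, d)
        res = ndim_components_weighted(b, min_component_size)
        samples[d] = res.value
        if collect_metadata:
            ks[d] = res.k
            comp = connected_components(b)[0]
            sub = b.subgraph(comp)
            pg = power_graph(sub, res.k)
            mult[d] = len(all_maximum_cliques(pg))
    return NdimDistribution(
        samples=samples,
        seed=spec.seed,
        n_samples=spec.n_samples,
        k_per_draw=ks,
        multiplicity_per_draw=mult,
    )


# ---------------------------------------------------------------------------
# 3. functional distances


def functional_distance_transform(w: WeightedGraph) -> np.ndarray:
    """Reciprocal map to functional distances: w̃ = 1/w, 0 -> inf.

    Strong connections become short distances; absent links become
    infinite ones.  The diagonal is 0 (self distance).
    """
    W = w.weights
    with np.errstate(divide="ignore"):
        wt = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(wt, 0.0)
    return wt


def multigraph_scale(wtilde: np.ndarray, spec: ScalingSpec | None = None) -> IntegerLengthGraph:
    """Integer-length approximating multigraph M = floor(c * w̃).

    c = kappa / (max finite w̃ - min positive w̃); infinite functional
    distances map to length 0 (no edge).  kappa must be large compared
    to max/min - 1 or rounding can destroy edges; a violation of the
    soft constraint logs a warning, and c * min < 1 (which would round a
    present edge to length 0) is an error.
    """
    spec = spec or ScalingSpec()
    wt = np.asarray(wtilde, dtype=float)
    off = ~np.eye(wt.shape[0], dtype=bool)
    finite = wt[off & np.isfinite(wt) & (wt > 0)]
    if finite.size == 0:
        raise ValueError("no finite positive functional distances")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise ValueError("degenerate weight range: all functional distances equal")
    ratio = hi / lo - 1.0
    if spec.kappa < 10.0 * ratio:
        logger.warning(
            "kappa=%.3g is not large compared to max/min - 1 = %.3g; "
            "integer rounding may distort distances",
            spec.kappa,
            ratio,
        )
    c = spec.kappa / (hi - lo)
    if c * lo < 1.0:
        raise ValueError(
            f"c*min = {c * lo:.3g} < 1 would erase edges; raise kappa above "
            f"{(hi - lo) / lo:.3g}"
        )
    M = np.where(np.isfinite(wt), np.floor(c * wt), 0.0).astype(np.int64)
    np.fill_diagonal(M, 0)
    return IntegerLengthGraph(M)


def distance_graph(m: IntegerLengthGraph) -> BinaryGraph:
    """Binary distance graph: edge iff shortest-path length <= floor(mu).

    mu is the mean shortest-path length over reachable distinct pairs
    (i.e. within components) of the multigraph.
    """
    if m.n < 2:
        raise ValueError("distance graph requires at least 2 nodes")
    summary = shortest_path_matrix(m)
    k = math.floor(summary.mu)
    D = summary.dist
    A = ((D > 0) & (D <= k)).astype(np.uint8)
    return BinaryGraph(A, labels=m.labels)


def ndim_functional(w: WeightedGraph, spec: ScalingSpec | None = None) -> NdimResult:
    """Ndim of a connected weighted graph via functional distances.

    Chain: w -> w̃ = 1/w -> integer multigraph M = floor(c·w̃) ->
    shortest-path matrix D (mu, m = minimum positive distance) ->
    binary distance graph (edge iff d <= floor(mu)) -> maximum clique ->
    Ndim = log|clique| / log((floor(mu)+m)/m).

    If the distance graph is disconnected, the maximum clique over all
    components is used.  When all positive weights are equal the graph
    is already binary up to a factor; lengths are set to 1 directly and
    the result coincides with the binary definition, as it must.
    """
    spec = spec or ScalingSpec()
    if len(connected_components(w.support())) > 1:
        raise ValueError("weighted graph is disconnected; apply per component")
    wt = functional_distance_transform(w)
    off = ~np.eye(wt.shape[0], dtype=bool)
    finite = wt[off & np.isfinite(wt) & (wt > 0)]
    if finite.size and float(finite.min()) == float(finite.max()):
        # uniform weights: the multigraph is the binary support graph
        M = IntegerLengthGraph((w.weights > 0).astype(np.int64), labels=w.labels)
    else:
        M = multigraph_scale(wt, spec)
        M = IntegerLengthGraph(M.lengths, labels=w.labels)
    summary = shortest_path_matrix(M)
    mu, m_min = summary.mu, summary.m_min
    k = math.floor(mu)
    D = summary.dist
    A = ((D > 0) & (D <= k)).astype(np.uint8)
    G = BinaryGraph(A, labels=w.labels)

    best = None
    for comp in connected_components(G):
        if comp.size == 0:
            continue
        res = max_clique(G.subgraph(comp))
        if best is None or res.cardinality > best.cardinality:
            best = res
    if best is None:
        raise ValueError("distance graph has no nodes")
    value = ndim_from_distance_data(best.cardinality, mu, m_min)
    return NdimResult(
        value=value,
        mu=mu,
        k=k,
        m_min=m_min,
        clique_cardinality=best.cardinality,
        clique_vertices=best.vertices,
    )
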