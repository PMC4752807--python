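"""Ensemble comparison statistics and core-node analysis.

A *core node* of a binary graph (at scale k) is a node contained in the
intersection of all maximum k-cliques — a hub lying within distance k of
every maximum k-clique member.  Across a Monte-Carlo ensemble of binary
realisations of a weighted network, each node gets a probability of
being a core node; in functional connectivity networks these
probabilities localise the regions that drive complexity differences.

Distribution shifts between two Ndim ensembles are tested with the
Brunner–Munzel rank statistic, which makes no assumption about the
shapes of the two distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from netdim.clique import all_maximum_cliques
from netdim.graph_core import BinaryGraph, WeightedGraph, connected_components, power_graph, shortest_path_matrix
from netdim.weighted import EnsembleSpec, ThresholdSpec, mc_sample, threshold_weights

__all__ = ["CoreNodeProfile", "core_nodes", "core_node_probabilities", "brunner_munzel"]


@dataclass
class CoreNodeProfile:
    """Per-node core probabilities over an ensemble, plus per-draw metadata."""

    labels: tuple
    probabilities: np.ndarray
    k_per_draw: np.ndarray
    multiplicity_per_draw: np.ndarray
    n_samples: int

    @property
    def multiplicity_median(self) -> float:
        return float(np.median(self.multiplicity_per_draw))

    @property
    def k_median(self) -> float:
        return float(np.median(self.k_per_draw))


def core_nodes(g: BinaryGraph, k: int, cap: int = 10**6) -> set:
    """Intersection of all maximum k-cliques of a connected graph.

    May be empty (e.g. a 4-cycle at k = 1, whose four maximum 1-cliques
    are its edges).  Raises if the clique enumeration exceeds ``cap``.
    """
    if len(connected_components(g)) > 1:
        raise ValueError("core nodes require a connected graph")
    cliques = all_maximum_cliques(power_graph(g, k), cap=cap)
    core = set(cliques[0].vertices)
    for c in cliques[1:]:
        core &= set(c.vertices)
        if not core:
            break
    return core


def core_node_probabilities(
    w: WeightedGraph,
    spec: EnsembleSpec,
    pre_threshold: ThresholdSpec | None = None,
    min_component_size: int = 5,
    cap: int = 10**6,
) -> CoreNodeProfile:
    """Probability of each node to be a core node across the ensemble.

    Per draw, the largest retained component of the sampled binary graph
    is analysed: its k = floor(mu), its maximum k-cliques, and their
    intersection.  The probability of a node is the fraction of draws in
    which it was a core node; the per-draw clique multiplicity and k are
    recorded (their medians summarise ensemble structure).
    """
    if pre_threshold is not None:
        w = threshold_weights(w, pre_threshold)
    pos = {lab: i for i, lab in enumerate(w.labels)}
    counts = np.zeros(w.n, dtype=np.int64)
    ks = np.zeros(spec.n_samples, dtype=np.int64)
    mult = np.zeros(spec.n_samples, dtype=np.int64)
    for d in range(spec.n_samples):
        b = mc_sample(w, spec, d)
        comps = [c for c in connected_components(b) if c.size >= max(min_component_size, 2)]
        if not comps:
            continue  # draw carries no informative component
        comp = comps[0]
        sub = b.subgraph(comp)
        summary = shortest_path_matrix(sub)
        k = max(summary.k, 1)
        cliques = all_maximum_cliques(power_graph(sub, k, dist=summary.dist), cap=cap)
        ks[d] = k
        mult[d] = len(cliques)
        core = set(cliques[0].vertices)
        for c in cliques[1:]:
            core &= set(c.vertices)
            if not core:
                break
        for lab in core:
            counts[pos[lab]] += 1
    return CoreNodeProfile(
        labels=w.labels,
        probabilities=counts / spec.n_samples,
        k_per_draw=ks,
        multiplicity_per_draw=mult,
        n_samples=spec.n_samples,
    )


def brunner_munzel(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Brunner–Munzel rank test for a stochastic shift between two samples.

    Returns ``(statistic, p_value, phat)`` where
    phat = P(X < Y) + 0.5·P(X = Y) is the stochastic-superiority
    estimate (0.5 under exchangeability).  ``alternative`` states the
    direction of the shift being tested, referring to ``x`` relative to
    ``y``: ``"less"`` means the distribution of X lies stochastically
    below that of Y (phat > 0.5), ``"greater"`` the reverse.  The
    statistic uses midranks and a Satterthwaite-type t approximation for
    the degrees of freedom, and is therefore free of any distributional
    shape assumption.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("both samples need at least 2 observations")
    if nx < 10 or ny < 10:
        warnings.warn("Brunner-Munzel approximation is unreliable below ~10 per sample")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        raise ValueError("degenerate input: all observations identical")
    rank_all = sstats.rankdata(combined)  # midranks
    rx, ry = rank_all[:nx], rank_all[nx:]
    rx_within = sstats.rankdata(x)
    ry_within = sstats.rankdata(y)
    mx, my = rx.mean(), ry.mean()
    phat = (my - (ny + 1) / 2.0) / nx
    sx2 = np.sum((rx - rx_within - mx + (nx + 1) / 2.0) ** 2) / (nx - 1)
    sy2 = np.sum((ry - ry_within - my + (ny + 1) / 2.0) ** 2) / (ny - 1)
    if sx2 == 0 and sy2 == 0:
        raise ValueError("degenerate input: zero rank variance in both samples")
    sigma2 = nx * sx2 + ny * sy2
    statistic = (my - mx) * nx * ny / ((nx + ny) * np.sqrt(sigma2))
    df = sigma2**2 / ((nx * sx2) ** 2 / (nx - 1) + (ny * sy2) ** 2 / (ny - 1))
    if alternative == "two-sided":
        p = 2 * sstats.t.sf(abs(statistic), df)
    elif alternative == "less":  # H1: X stochastically less than Y (phat > 0.5)
        p = sstats.t.sf(statistic, df)
    elif alternative == "greater":
        p = sstats.t.cdf(statistic, df)
    else:
        raise ValueError("alternative must be 'two-sided', 'greater' or 'less'")
    return float(statistic), float(p), float(phat)
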