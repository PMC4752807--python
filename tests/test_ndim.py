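import math

import numpy as np
import pytest

from netdim import BinaryGraph
from netdim.graph_core import power_graph, shortest_path_matrix
from netdim.clique import max_clique
from netdim.models import lattice_graph
from netdim.ndim import (
    ndim_binary,
    ndim_components_weighted,
    ndim_from_distance_data,
    ndim_growth_sequence,
)

from conftest import complete_graph, random_graph


class TestFormula:
    def test_binary_reduction(self):
        assert ndim_from_distance_data(34, 33.67, 1.0) == pytest.approx(
            math.log(34) / math.log(34)
        )

    def test_single_node_clique_zero(self):
        assert ndim_from_distance_data(1, 5.0, 1.0) == 0.0

    def test_generalised(self):
        # clique 2, floor(mu)=200, m=100 -> log 2 / log 3
        assert ndim_from_distance_data(2, 200.0, 100.0) == pytest.approx(
            math.log(2) / math.log(3)
        )

    def test_invalid(self):
        with pytest.raises(ValueError):
            ndim_from_distance_data(0, 1.0, 1.0)
        with pytest.raises(ValueError):
            ndim_from_distance_data(2, 1.0, 0.0)


class TestNdimBinary:
    @pytest.mark.parametrize("n", [2, 4, 8, 16, 32])
    def test_complete_closed_form(self, n):
        r = ndim_binary(complete_graph(n))
        assert r.value == pytest.approx(math.log(n) / math.log(2))
        assert r.k == 1 and r.clique_cardinality == n

    def test_two_node_graph(self):
        r = ndim_binary(BinaryGraph.from_edges([(0, 1)]))
        assert r.value == 1.0 and r.mu == 1.0

    def test_c5(self, c5):
        # mu = 1.5 -> k = 1, max clique = an edge
        r = ndim_binary(c5)
        assert r.k == 1 and r.clique_cardinality == 2 and r.value == 1.0

    def test_path10(self):
        # mu = 11/3 -> k = 3, clique = 4 consecutive nodes
        r = ndim_binary(lattice_graph([10]))
        assert r.value == 1.0 and r.k == 3

    def test_disconnected_errors(self):
        g = BinaryGraph.from_edges([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            ndim_binary(g)

    def test_half_diameter_mode(self):
        g = lattice_graph([10])
        r = ndim_binary(g, k_mode="half_diameter")
        assert r.k == 4  # diameter 9 -> floor(9/2)
        assert r.clique_cardinality == 5

    def test_clique_is_valid_k_clique(self):
        for seed in range(5):
            g = random_graph(15, 0.3, seed)
            s = shortest_path_matrix(g)
            if not s.connected:
                continue
            r = ndim_binary(g)
            idx = {lab: i for i, lab in enumerate(g.labels)}
            vs = [idx[v] for v in r.clique_vertices]
            for i, u in enumerate(vs):
                for v in vs[i + 1 :]:
                    assert s.dist[u, v] <= r.k


class TestComponentsWeighted:
    def test_connected_matches_binary(self, c5):
        a = ndim_binary(c5)
        b = ndim_components_weighted(c5, min_component_size=2)
        assert b.value == a.value
        assert b.component_weights == [(5, a.value, 1.0)]

    def test_two_components_weighted_mean(self):
        # K6 plus K8, both retained: weights 6/14 and 8/14
        A = np.zeros((14, 14), dtype=np.uint8)
        A[:6, :6] = 1 - np.eye(6, dtype=np.uint8)
        A[6:, 6:] = 1 - np.eye(8, dtype=np.uint8)
        g = BinaryGraph(A)
        r = ndim_components_weighted(g, min_component_size=5)
        expect = (8 / 14) * 3.0 + (6 / 14) * math.log2(6)
        assert r.value == pytest.approx(expect)

    def test_small_components_dropped(self):
        # K8 plus an isolated edge: the pair is below the default cutoff
        A = np.zeros((10, 10), dtype=np.uint8)
        A[:8, :8] = 1 - np.eye(8, dtype=np.uint8)
        A[8, 9] = A[9, 8] = 1
        r = ndim_components_weighted(BinaryGraph(A))
        assert r.value == 3.0
        assert r.component_weights == [(8, 3.0, 1.0)]

    def test_nothing_retained_errors(self):
        g = BinaryGraph.from_edges([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            ndim_components_weighted(g, min_component_size=5)


class TestGrowthSequence:
    def test_matches_unseeded(self):
        graphs = [lattice_graph([n]) for n in (10, 20, 40)]
        seeded = ndim_growth_sequence(graphs)
        plain = [ndim_binary(g) for g in graphs]
        assert [r.value for r in seeded] == [r.value for r in plain]

    def test_survives_invalid_seed_assumption(self):
        # shrinking sequence: the monotonicity seed does not hold, results
        # must still be exact because the stage is recomputed unseeded
        graphs = [complete_graph(16), lattice_graph([10])]
        rs = ndim_growth_sequence(graphs)
        assert rs[0].value == 4.0
        assert rs[1].value == 1.0


class TestMonotonicityProperties:
    def test_monotone_under_induced_subgraphs(self):
        # fixed (mu, m): the max k-clique of an induced subgraph of the
        # power graph never exceeds the full graph's
        rng = np.random.default_rng(0)
        checked = 0
        for seed in range(30):
            g = random_graph(16, 0.3, seed)
            s = shortest_path_matrix(g)
            if not s.connected:
                continue
            k = max(s.k, 1)
            pg = power_graph(g, k, dist=s.dist)
            full = max_clique(pg).cardinality
            for _ in range(5):
                keep = np.sort(rng.choice(16, size=int(rng.integers(2, 16)), replace=False))
                A = pg.adjacency.toarray()[np.ix_(keep, keep)]
                sub = BinaryGraph(A)
                assert max_clique(sub).cardinality <= full
                checked += 1
        assert checked >= 100

    def test_quasi_maximum_sandwich(self):
        # decomposition G = G1 (+) G2 at fixed (mu, m):
        # quasi-maximum property: max(N1, N2) <= N <= max(N1, N2) + 1/log2(k+1)
        rng = np.random.default_rng(1)
        checked = 0
        seed = 0
        while checked < 200:
            seed += 1
            g = random_graph(14, 0.35, seed)
            s = shortest_path_matrix(g)
            if not s.connected:
                continue
            k = max(s.k, 1)
            pg = power_graph(g, k, dist=s.dist)
            A = pg.adjacency.toarray()
            full = max_clique(pg).cardinality
            nd = math.log(full) / math.log(k + 1)
            for _ in range(4):
                mask = rng.random(14) < 0.5
                if mask.all() or not mask.any():
                    continue
                parts = []
                for sel in (mask, ~mask):
                    if sel.sum() == 0:
                        parts.append(1)  # empty part: clique cardinality 1 floor
                        continue
                    sub = BinaryGraph(A[np.ix_(sel.nonzero()[0], sel.nonzero()[0])])
                    parts.append(max_clique(sub).cardinality)
                best = max(math.log(c) / math.log(k + 1) for c in parts)
                assert best <= nd + 1e-12
                assert nd <= best + 1.0 / math.log2(k + 1) + 1e-12
                checked += 1
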