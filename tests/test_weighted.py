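import math

import numpy as np
import pytest

from netdim import BinaryGraph, WeightedGraph
from netdim.models import synthetic_correlation_matrix
from netdim.ndim import ndim_binary
from netdim.weighted import (
    EnsembleSpec,
    ScalingSpec,
    ThresholdSpec,
    distance_graph,
    functional_distance_transform,
    mc_ndim_distribution,
    mc_sample,
    multigraph_scale,
    ndim_functional,
    ndim_thresholded,
    threshold_binarize,
)


def triangle_weights():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = 0.1
    W[1, 2] = W[2, 1] = 0.3
    return WeightedGraph(W)


class TestThreshold:
    def test_above(self):
        g = threshold_binarize(triangle_weights(), ThresholdSpec(tau=0.2, mode="above"))
        assert {tuple(sorted(e)) for e in g.edges()} == {(0, 1), (1, 2)}

    def test_below(self):
        g = threshold_binarize(triangle_weights(), ThresholdSpec(tau=0.2, mode="below"))
        assert {tuple(sorted(e)) for e in g.edges()} == {(0, 2)}

    def test_tiny_tau_gives_support(self):
        g = threshold_binarize(triangle_weights(), ThresholdSpec(tau=1e-6, mode="above"))
        assert g.edge_count == 3

    def test_zero_weight_never_edge_below(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.1
        g = threshold_binarize(WeightedGraph(W), ThresholdSpec(tau=0.5, mode="below"))
        assert g.edge_count == 1  # only the positive weight, not the zeros

    def test_tau_positive(self):
        with pytest.raises(ValueError):
            ThresholdSpec(tau=0.0, mode="above")

    def test_monotone_edge_set_in_tau(self):
        w = synthetic_correlation_matrix(30, [15, 15], noise_sd=0.2, seed=5)
        prev = None
        for tau in (0.6, 0.4, 0.2):
            g = threshold_binarize(w, ThresholdSpec(tau=tau, mode="above"))
            if prev is not None:
                assert g.edge_count >= prev
            prev = g.edge_count


class TestNdimThresholded:
    def test_complete_block(self):
        K8 = WeightedGraph(0.9 * (1 - np.eye(8)))
        r = ndim_thresholded(K8, ThresholdSpec(tau=0.2, mode="above"))
        assert r.value == 3.0

    def test_two_block(self):
        w = synthetic_correlation_matrix(40, [20, 20], within_weight=0.8, between_weight=0.05, noise_sd=0.0, seed=0)
        r = ndim_thresholded(w, ThresholdSpec(tau=0.2, mode="above"))
        assert r.value == pytest.approx(math.log(20) / math.log(2))
        assert len(r.component_weights) == 2

    def test_tau_above_max_errors(self):
        w = triangle_weights()
        with pytest.raises(ValueError):
            ndim_thresholded(w, ThresholdSpec(tau=0.9, mode="above"))


class TestMonteCarlo:
    def test_deterministic_weights(self):
        K8 = WeightedGraph(1.0 * (1 - np.eye(8)))
        spec = EnsembleSpec(n_samples=20, seed=11, joint_max=1.0)
        d = mc_ndim_distribution(K8, spec)
        assert set(d.samples) == {3.0}
        assert d.n_samples == 20

    def test_sample_reproducible(self):
        w = synthetic_correlation_matrix(20, [10, 10], noise_sd=0.2, seed=2)
        spec = EnsembleSpec(n_samples=5, seed=42, joint_max=1.0)
        a = mc_sample(w, spec, 3)
        b = mc_sample(w, spec, 3)
        assert np.array_equal(a.adjacency.toarray(), b.adjacency.toarray())
        c = mc_sample(w, spec, 4)
        assert not np.array_equal(a.adjacency.toarray(), c.adjacency.toarray())

    def test_distribution_reproducible(self):
        w = synthetic_correlation_matrix(16, [8, 8], noise_sd=0.15, seed=7)
        spec = EnsembleSpec(n_samples=40, seed=9, joint_max=1.0)
        d1 = mc_ndim_distribution(w, spec)
        d2 = mc_ndim_distribution(w, spec)
        assert np.array_equal(d1.samples, d2.samples)

    def test_marginal_calibration(self):
        # empirical edge frequency matches the normalized weight at 3 sigma
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        w = WeightedGraph(W)
        spec = EnsembleSpec(n_samples=10_000, seed=3, joint_max=1.0)
        freq = sum(mc_sample(w, spec, d).edge_count for d in range(10_000)) / 10_000
        assert freq == pytest.approx(0.3, abs=0.015)

    def test_normalization_error(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.8
        spec = EnsembleSpec(n_samples=2, seed=0, joint_max=0.5)
        with pytest.raises(ValueError):
            mc_sample(WeightedGraph(W), spec, 0)

    def test_noise_recovery(self):
        clean = synthetic_correlation_matrix(30, [15, 15], within_weight=0.9, between_weight=0.0, noise_sd=0.0, seed=0)
        noisy = synthetic_correlation_matrix(30, [15, 15], within_weight=0.9, between_weight=0.0, noise_sd=0.03, seed=1)
        spec = EnsembleSpec(n_samples=150, seed=5, joint_max=1.0)
        pre = ThresholdSpec(tau=0.3, mode="above")
        ref = np.mean(mc_ndim_distribution(clean, spec, pre_threshold=pre).samples)
        got = np.mean(mc_ndim_distribution(noisy, spec, pre_threshold=pre).samples)
        assert got == pytest.approx(ref, abs=0.15)


class TestFunctional:
    def test_reciprocal(self):
        w = triangle_weights()
        f = functional_distance_transform(w)
        assert f[0, 1] == pytest.approx(2.0)
        assert np.isinf(functional_distance_transform(WeightedGraph(np.zeros((2, 2))))[0, 1])

    def test_multigraph_scale_example(self):
        # wtilde in {2, 4}, kappa=100 -> c = 50, lengths {100, 200}
        wt = np.array([[np.inf, 2.0, np.inf], [2.0, np.inf, 4.0], [np.inf, 4.0, np.inf]])
        m = multigraph_scale(wt, ScalingSpec(kappa=100))
        assert m.lengths[0, 1] == 100 and m.lengths[1, 2] == 200

    def test_degenerate_range_errors(self):
        wt = np.array([[np.inf, 3.0], [3.0, np.inf]])
        with pytest.raises(ValueError):
            multigraph_scale(wt, ScalingSpec(kappa=100))

    def test_low_kappa_errors_when_edges_vanish(self):
        wt = np.array([[np.inf, 1.0, np.inf], [1.0, np.inf, 500.0], [np.inf, 500.0, np.inf]])
        with pytest.raises(ValueError):
            multigraph_scale(wt, ScalingSpec(kappa=100))

    def test_kappa_warning(self, caplog):
        wt = np.array([[np.inf, 10.0, np.inf], [10.0, np.inf, 11.0], [np.inf, 11.0, np.inf]])
        with caplog.at_level("WARNING", logger="netdim.weighted"):
            multigraph_scale(wt, ScalingSpec(kappa=0.2))
        assert any("rounding" in rec.message for rec in caplog.records)

    def test_distance_graph_chain(self):
        # lengths 100, 200: d = {100, 200, 300}, mu = 200 -> edges {01, 12}
        L = np.zeros((3, 3), dtype=np.int64)
        L[0, 1] = L[1, 0] = 100
        L[1, 2] = L[2, 1] = 200
        from netdim.graph_core import IntegerLengthGraph

        g = distance_graph(IntegerLengthGraph(L))
        assert {tuple(sorted(e)) for e in g.edges()} == {(0, 1), (1, 2)}

    def test_chain_value(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.25
        r = ndim_functional(WeightedGraph(W), ScalingSpec(kappa=100))
        assert r.value == pytest.approx(math.log(2) / math.log(3))
        assert r.m_min == 100.0 and r.k == 200

    def test_scale_invariance(self):
        w = synthetic_correlation_matrix(20, [10, 10], noise_sd=0.1, seed=3)
        spec = ScalingSpec(kappa=10_000)
        base = ndim_functional(w, spec).value
        for lam in (0.5, 3.0, 17.0):
            scaled = WeightedGraph(lam * w.weights)
            assert ndim_functional(scaled, spec).value == pytest.approx(base, abs=0.0)

    def test_binary_consistency(self):
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (1, 3)]
        A = np.zeros((5, 5))
        for a, b in edges:
            A[a, b] = A[b, a] = 1.0
        binary = ndim_binary(BinaryGraph(A.astype(np.uint8)))
        functional = ndim_functional(WeightedGraph(A))
        assert functional.value == pytest.approx(binary.value, abs=1e-12)
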