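import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spacc import (RunConfig, ValidationError, WeightChain, extract_partition,
                   fit_spacc, gamma_full_fusion, group_soft_threshold,
                   spacc_objective)
from spacc.solver import _ama_chain

from ._oracle import oracle_solve
from .conftest import random_instance


def unit_chain(p):
    return WeightChain(weights=np.ones(p - 1), distances=np.ones(p - 1),
                       segments=[])


class TestGroupSoftThreshold:
    @pytest.mark.parametrize("g, t, expected", [
        ((3.0, 4.0), 5.0, (0.0, 0.0)),       # at the boundary ||g|| = t
        ((3.0, 4.0), 2.5, (1.5, 2.0)),       # factor 1 - 2.5/5 = 0.5
        ((0.0, 0.0), 1.0, (0.0, 0.0)),       # zero vector stays zero
    ])
    def test_examples(self, g, t, expected):
        np.testing.assert_allclose(group_soft_threshold(np.array(g), t),
                                   expected, atol=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=5))
    def test_zero_threshold_is_identity(self, g):
        g = np.asarray(g)
        np.testing.assert_array_equal(group_soft_threshold(g, 0.0), g)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValidationError):
            group_soft_threshold(np.ones(2), -0.1)


class TestObjective:
    def test_hand_value(self):
        X = np.array([[0.0, 2.0]])
        U = np.array([[0.5, 1.5]])
        val = spacc_objective(X, U, unit_chain(2), gamma=0.5)
        assert val == pytest.approx(0.75)

    def test_zero_at_gamma_zero_with_u_equal_x(self, rng):
        X, chain = random_instance(rng)
        assert spacc_objective(X, X, chain, 0.0) == 0.0

    def test_penalty_only_when_u_equals_x(self, rng):
        X, chain = random_instance(rng)
        diffs = np.sqrt(((X[:, :-1] - X[:, 1:]) ** 2).sum(axis=0))
        expected = 2.0 * (chain.weights * diffs).sum()
        assert spacc_objective(X, X, chain, 2.0) == pytest.approx(expected)

    def test_nan_in_u_rejected(self, rng):
        X, chain = random_instance(rng)
        U = X.copy()
        U[0, 0] = np.nan
        with pytest.raises(ValidationError):
            spacc_objective(X, U, chain, 1.0)


class TestFitLimits:
    def test_gamma_zero_returns_x_exactly(self, rng):
        X, chain = random_instance(rng)
        fit = fit_spacc(X, chain, 0.0)
        np.testing.assert_array_equal(fit.U, X)

    @pytest.mark.parametrize("gamma, expected", [
        (0.3, (0.3, 1.7)), (0.9, (0.9, 1.1)), (1.0, (1.0, 1.0)),
        (3.0, (1.0, 1.0)),
    ])
    def test_two_point_closed_form(self, gamma, expected):
        # X = (0, 2), w = 1: U = (gamma, 2 - gamma) for gamma <= 1, fused above
        X = np.array([[0.0, 2.0]])
        fit = fit_spacc(X, unit_chain(2), gamma, tol=1e-10)
        np.testing.assert_allclose(fit.U, [list(expected)], atol=1e-6)

    def test_full_fusion_returns_segment_means(self, rng):
        X, chain = random_instance(rng, n=2, p=8)
        chain.weights[3] = 0.0
        chain = WeightChain(chain.weights, chain.distances, segments=[])
        gamma = gamma_full_fusion(X, chain) * 1.001
        fit = fit_spacc(X, chain, gamma, tol=1e-9)
        for (s, e) in chain.segments:
            seg_mean = X[:, s:e].mean(axis=1, keepdims=True)
            np.testing.assert_allclose(fit.U[:, s:e],
                                       np.broadcast_to(seg_mean, (2, e - s)),
                                       atol=1e-5)

    def test_gamma_full_fusion_is_sharp(self, rng):
        X, chain = random_instance(rng, n=2, p=5)
        gmax = gamma_full_fusion(X, chain)
        below = fit_spacc(X, chain, 0.98 * gmax, tol=1e-10)
        above = fit_spacc(X, chain, 1.02 * gmax, tol=1e-10)
        assert np.abs(above.V).max() < 1e-6
        assert np.abs(below.V).max() > 1e-6


class TestOracleEquivalence:
    def test_matches_generic_convex_solver(self, rng):
        """AMA objective matches an independent smoothed L-BFGS solve."""
        for _ in range(20):
            n = int(rng.integers(1, 4))
            p = int(rng.integers(2, 7))
            X, chain = random_instance(rng, n=n, p=p)
            gamma = float(rng.uniform(0.05, 2.0))
            fit = fit_spacc(X, chain, gamma, tol=1e-10)
            f_ama = spacc_objective(X, fit.U, chain, gamma)
            f_star, _ = oracle_solve(X, chain.weights, gamma)
            assert f_ama <= f_star * (1 + 1e-5) + 1e-8
            assert abs(f_ama - f_star) <= 1e-5 * (1 + abs(f_star))


class TestSolverProperties:
    def test_scale_equivariance(self, rng):
        X, chain = random_instance(rng)
        c = 3.7
        f1 = fit_spacc(X, chain, 0.4, tol=1e-10)
        f2 = fit_spacc(c * X, chain, 0.4 * c, tol=1e-10)
        np.testing.assert_allclose(c * f1.U, f2.U, atol=1e-5)

    def test_subject_permutation_equivariance(self, rng):
        X, chain = random_instance(rng, n=4, p=5)
        perm = np.array([2, 0, 3, 1])
        f1 = fit_spacc(X, chain, 0.5, tol=1e-10)
        f2 = fit_spacc(X[perm], chain, 0.5, tol=1e-10)
        np.testing.assert_allclose(f1.U[perm], f2.U, atol=1e-6)

    def test_fused_gap_set_nested_along_path(self, rng):
        X, chain = random_instance(rng, n=2, p=6)
        grid = np.geomspace(0.01, gamma_full_fusion(X, chain) * 1.1, 12)
        prev = np.zeros(5, dtype=bool)
        warm = None
        for gamma in grid:
            fit = fit_spacc(X, chain, gamma, warm=warm, tol=1e-9)
            warm = fit
            fused = (np.abs(fit.V) < 1e-7).all(axis=0)
            assert (prev <= fused).all()   # fusions only grow with gamma
            prev = fused

    def test_objective_trace_monotone_after_burn_in(self, rng):
        X, chain = random_instance(rng, n=2, p=6)
        cfg = RunConfig(accelerate=False)
        fit = fit_spacc(X, chain, 0.6, config=cfg, record_trace=True,
                        tol=1e-10)
        trace = fit.objective_trace
        assert (trace >= 0).all()
        burn = min(20, len(trace) // 2)
        tail = trace[burn:]
        assert (np.diff(tail) <= 1e-9 * (1 + np.abs(tail[:-1]))).all()

    def test_numpy_and_numba_paths_agree(self, rng):
        X, chain = random_instance(rng, n=3, p=7)
        fit = fit_spacc(X, chain, 0.7, tol=1e-10)           # numba kernel
        U2, V2, L2, _, _, _ = _ama_chain(                    # numpy reference
            X, chain.weights, 0.7, 0.25, 1e-10, 50000,
            accelerate=True, warm=None, record_trace=True)
        np.testing.assert_allclose(fit.U, U2, atol=1e-7)

    def test_non_finite_input_rejected(self, rng):
        X, chain = random_instance(rng)
        X[0, 0] = np.inf
        with pytest.raises(ValidationError):
            fit_spacc(X, chain, 0.1)


class TestExtractPartition:
    def make_probes(self, p):
        from spacc import ProbeMatrix
        return ProbeMatrix.from_arrays(values=np.zeros((2, p)),
                                       chrom=["chr1"] * p,
                                       pos=list(range(1, p + 1)))

    def test_all_zero_v_fuses_each_segment(self, rng):
        X, chain = random_instance(rng, n=2, p=6)
        chain.weights[2] = 0.0
        chain = WeightChain(chain.weights, chain.distances, segments=[])
        gamma = gamma_full_fusion(X, chain) * 1.01
        fit = fit_spacc(X, chain, gamma, tol=1e-9)
        part = extract_partition(fit, chain, threshold_level=1e-6,
                                 probes=self.make_probes(6))
        np.testing.assert_array_equal(part.assignment, [0, 0, 0, 1, 1, 1])

    def test_zero_threshold_splits_at_nonzero_column(self, rng):
        X, chain = random_instance(rng, n=2, p=5)
        fit = fit_spacc(X, chain, 0.01, tol=1e-10)
        V = np.zeros_like(fit.V)
        V[:, 2] = [0.5, -0.2]
        fit.V = V
        part = extract_partition(fit, chain, 0.0, self.make_probes(5))
        np.testing.assert_array_equal(part.assignment, [0, 0, 0, 1, 1])

    def test_small_entries_zeroed_elementwise(self, rng):
        X, chain = random_instance(rng, n=2, p=3)
        fit = fit_spacc(X, chain, 0.01)
        fit.V = np.array([[0.001, 0.5], [-0.002, 0.4]])
        part = extract_partition(fit, chain, 0.01, self.make_probes(3))
        np.testing.assert_array_equal(part.assignment, [0, 0, 1])

    def test_entry_exactly_at_level_survives(self, rng):
        X, chain = random_instance(rng, n=1, p=2)
        fit = fit_spacc(X, chain, 0.01)
        fit.V = np.array([[0.01]])
        part = extract_partition(fit, chain, 0.01, self.make_probes(2))
        assert part.n_regions == 2
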