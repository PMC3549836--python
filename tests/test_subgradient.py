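"""Conditional-subgradient solver: subgradient validity, subproblem, rounding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import blockmod as bm
from blockmod.exceptions import ValidationError
from blockmod.objective import xs_product
from blockmod.subgradient import _relaxed_F

from conftest import random_er_network


class TestSignMatrix:
    def test_direct_rule(self):
        Q = np.array([[2.0, 0.0], [0.0, -3.0]])
        assert np.array_equal(bm.sign_matrix(Q, 0.0),
                              np.array([[1.0, 0.0], [0.0, -1.0]]))

    def test_all_zero_alpha_one(self):
        Qbar = bm.sign_matrix(np.zeros((3, 3)), 1.0)
        assert np.array_equal(Qbar, np.ones((3, 3)))
        assert np.abs(Qbar).max() == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(Q=arrays(float, (4, 4), elements=st.floats(-5, 5)),
           alpha=st.floats(-1, 1))
    def test_inner_product_recovers_l1_norm(self, Q, alpha):
        Qbar = bm.sign_matrix(Q, alpha)
        assert np.abs(Qbar).max() <= 1.0
        assert (Qbar * Q).sum() == pytest.approx(np.abs(Q).sum(), abs=1e-9)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValidationError):
            bm.sign_matrix(np.zeros((2, 2)), 1.5)


class TestSubgrad:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_finite_differences_where_smooth(self, seed):
        # at interior points with all |Q_rs| bounded away from 0 and mixed
        # signs, F is differentiable and the subgradient is the gradient
        rng = np.random.default_rng(seed)
        net = random_er_network(10, 0.4, seed % 5)
        nm = bm.null_model(net)
        while True:
            tau = rng.integers(0, 3, size=10)
            H = np.zeros((10, 3))
            H[np.arange(10), tau] = 1.0
            S = 0.85 * H + 0.15 * rng.dirichlet(np.ones(3), size=10)
            Q = S.T @ xs_product(net, nm, S)
            if np.abs(Q).min() > 1e-6 and (Q > 0).any() and (Q < 0).any():
                break
        D = rng.normal(size=(10, 3))
        D -= D.mean(axis=1, keepdims=True)  # feasible direction: row sums 0
        D /= np.linalg.norm(D)
        g = bm.subgrad(net, nm, S, 0.0) / (2.0 * nm.M)  # normalized F scale
        h = 1e-6
        fd = (_relaxed_F(net, nm, S + h * D) - _relaxed_F(net, nm, S - h * D)) / (2 * h)
        an = float((g * D).sum())
        assert abs(fd - an) <= 1e-5 * max(abs(fd), abs(an))

    @pytest.mark.parametrize("seed", range(3))
    def test_rank_one_path_matches_dense_formula(self, seed):
        # the lazily-evaluated (P - W) S product must agree with the dense
        # 2(P - W) S Qbar formula with an explicitly zeroed diagonal
        net = random_er_network(8, 0.5, seed)
        nm = bm.null_model(net)
        S = np.random.default_rng(seed).dirichlet(np.ones(3), size=8)
        X = net.weights.toarray() - nm.dense_p()
        np.fill_diagonal(X, 0.0)
        expected = -2.0 * X @ S @ bm.sign_matrix(S.T @ X @ S, 0.0)
        assert bm.subgrad(net, nm, S, 0.0) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("scale", [2.0, 10.0])
    def test_homogeneous_in_weight_scale(self, scale, two_triangles):
        nm1 = bm.null_model(two_triangles)
        scaled = bm.Network.from_dense(scale * two_triangles.weights.toarray())
        nm2 = bm.null_model(scaled)
        rng = np.random.default_rng(0)
        S = rng.dirichlet(np.ones(2), size=6)
        g1 = bm.subgrad(two_triangles, nm1, S, 0.0)
        g2 = bm.subgrad(scaled, nm2, S, 0.0)
        assert g2 == pytest.approx(scale * g1, rel=1e-9)


class TestLinearSubproblem:
    def test_rowwise_argmin(self):
        S = bm.linear_subproblem(np.array([[-1.0, 2.0], [3.0, -4.0]]))
        assert np.array_equal(S, np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_tie_goes_to_first_module(self):
        S = bm.linear_subproblem(np.array([[0.0, 0.0]]))
        assert np.array_equal(S, np.array([[1.0, 0.0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_beats_random_feasible_points(self, seed):
        rng = np.random.default_rng(seed)
        dF = rng.normal(size=(8, 3))
        S_star = bm.linear_subproblem(dF)
        val = (dF * S_star).sum()
        for _ in range(1000):
            S = rng.dirichlet(np.ones(3), size=8)
            assert val <= (dF * S).sum() + 1e-12


class TestLineSearch:
    def test_identical_endpoints_leave_f_unchanged(self, two_triangles):
        nm = bm.null_model(two_triangles)
        S = np.full((6, 2), 0.5)
        lam, S_out, F = bm.line_search(two_triangles, nm, S, S)
        assert F == pytest.approx(_relaxed_F(two_triangles, nm, S))

    @pytest.mark.parametrize("seed", range(5))
    def test_never_worse_than_either_endpoint(self, seed):
        net = random_er_network(9, 0.4, seed)
        nm = bm.null_model(net)
        rng = np.random.default_rng(seed)
        S0 = rng.dirichlet(np.ones(3), size=9)
        S1 = bm.init_assignment(net, 3, "random_hard", seed)
        lam, S_out, F = bm.line_search(net, nm, S0, S1)
        assert 0.0 <= lam <= 1.0
        assert F <= _relaxed_F(net, nm, S0) + 1e-12
        assert F <= _relaxed_F(net, nm, S1) + 1e-12
        assert F == pytest.approx(_relaxed_F(net, nm, S_out), abs=1e-12)

    def test_one_iteration_improves_from_uniform(self, two_triangles):
        nm = bm.null_model(two_triangles)
        S = np.full((6, 2), 0.5)
        F0 = _relaxed_F(two_triangles, nm, S)
        dF = bm.subgrad(two_triangles, nm, S, 1.0)  # alpha=1 escapes the flat Q=0
        S_star = bm.linear_subproblem(dF)
        _, S1, F1 = bm.line_search(two_triangles, nm, S, S_star)
        assert F1 <= F0 + 1e-12


class TestRounding:
    @pytest.mark.parametrize("S,expected", [
        ([[0.6, 0.4], [0.2, 0.8]], [0, 1]),
        ([[0.5, 0.5]], [0]),  # tie to smallest module index
    ])
    def test_argmax_with_ties(self, S, expected):
        assert np.array_equal(bm.round_assignment(np.array(S)).tau, expected)

    def test_idempotent_on_hard_assignments(self):
        rng = np.random.default_rng(1)
        tau = rng.integers(0, 4, size=12)
        asg = bm.Assignment(tau, 4)
        assert np.array_equal(bm.round_assignment(asg.S).tau, tau)


class TestInitAssignment:
    @pytest.mark.parametrize("method", ["random_hard", "random_soft", "degree_stripe"])
    def test_deterministic_and_feasible(self, method, two_triangles):
        S1 = bm.init_assignment(two_triangles, 3, method, seed=7)
        S2 = bm.init_assignment(two_triangles, 3, method, seed=7)
        assert np.array_equal(S1, S2)
        assert S1.sum(axis=1) == pytest.approx(np.ones(6))
        assert S1.min() >= 0.0
        if method != "random_soft":
            assert set(np.unique(S1)) <= {0.0, 1.0}

    def test_q_one_forces_single_module(self, two_triangles):
        for method in ("random_hard", "random_soft", "degree_stripe"):
            S = bm.init_assignment(two_triangles, 1, method, seed=0)
            assert np.array_equal(S, np.ones((6, 1)))

    @pytest.mark.parametrize("q", [0, 7])
    def test_q_out_of_range(self, q, two_triangles):
        with pytest.raises(ValidationError):
            bm.init_assignment(two_triangles, q, "random_hard", 0)


class TestRunSg:
    def test_two_triangles_best_of_seeds_reaches_optimum(self, two_triangles):
        nm = bm.null_model(two_triangles)
        best = max(
            bm.run_sg(two_triangles, nm, 2,
                      bm.init_assignment(two_triangles, 2, "random_hard", s))[0].fitness
            for s in range(10))
        assert best == pytest.approx(7 / 12)

    def test_k22_best_of_seeds_finds_sparse_structure(self, k22):
        nm = bm.null_model(k22)
        sols = [bm.run_sg(k22, nm, 2,
                          bm.init_assignment(k22, 2, "random_hard", s))[0]
                for s in range(10)]
        best = max(sols, key=lambda s: s.fitness)
        assert best.fitness == pytest.approx(0.375)
        B = bm.image_graph(bm.block_matrix(k22, nm, best.assignment))
        assert np.array_equal(B, np.array([[0, 1], [1, 0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_trace_non_increasing(self, seed):
        net = random_er_network(12, 0.3, seed)
        nm = bm.null_model(net)
        _, trace = bm.run_sg(net, nm, 3,
                             bm.init_assignment(net, 3, "random_hard", seed))
        F = np.array(trace.F)
        assert (np.diff(F) <= 1e-12).all()

    @pytest.mark.parametrize("alpha", [-1.0, 0.0, 1.0])
    def test_alpha_choice_does_not_change_fixture_result(self, alpha, two_triangles):
        nm = bm.null_model(two_triangles)
        cfg = bm.SgConfig(alpha=alpha)
        best = max(
            bm.run_sg(two_triangles, nm, 2,
                      bm.init_assignment(two_triangles, 2, "random_hard", s),
                      cfg)[0].fitness
            for s in range(10))
        assert best == pytest.approx(7 / 12)

    def test_iterates_stay_feasible(self, two_triangles):
        # rounding a feasible relaxed point always yields a valid assignment;
        # exercised by running from a soft start
        nm = bm.null_model(two_triangles)
        sol, _ = bm.run_sg(two_triangles, nm, 3,
                           bm.init_assignment(two_triangles, 3, "random_soft", 0))
        assert sol.assignment.n == 6
        assert sol.fitness == pytest.approx(
            bm.fitness(two_triangles, nm, sol.assignment))
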