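"""Schrodinger-bridge solver: cost matrix, Sinkhorn, KL divergence."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from msbridge import (
    JointTransitionMatrix,
    TransportProblem,
    kl_divergence,
    sinkhorn_bridge,
    transition_cost_per_condition,
    transportation_cost_matrix,
)
from msbridge.exceptions import (
    InfeasibleMarginalsError,
    SupportViolationError,
)
from msbridge.sequences import CoverageDistribution
from tests.conftest import bridge_cost_bruteforce, plan_kl


def _jq(mat, n_pairs=1000):
    return JointTransitionMatrix(Q=np.asarray(mat, float), n_pairs=n_pairs)


def _solve(Qm, pi0, piT, **kw):
    prob = TransportProblem.from_distributions(_jq(Qm), np.asarray(pi0), np.asarray(piT))
    return sinkhorn_bridge(prob, **kw)


class TestCostMatrix:
    def test_uniform_q_gives_2_log_k(self):
        K = 4
        C, _ = transportation_cost_matrix(_jq(np.full((K, K), 1 / K**2)))
        np.testing.assert_allclose(C, 2 * np.log(K))

    def test_elementwise_negative_log(self):
        C, _ = transportation_cost_matrix(_jq([[0.4, 0.1], [0.2, 0.3]]))
        np.testing.assert_allclose(
            C, [[0.9163, 2.3026], [1.6094, 1.2040]], atol=5e-5
        )

    def test_zero_entry_infinite_cost(self):
        C, _ = transportation_cost_matrix(_jq([[0.5, 0.0], [0.25, 0.25]]))
        assert np.isinf(C[0, 1]) and np.isfinite(C).sum() == 3

    def test_pseudocount_smooths_counts(self):
        Q = _jq([[0.5, 0.0], [0.25, 0.25]], n_pairs=100)
        C, Qs = transportation_cost_matrix(Q, pseudocount=1.0)
        assert np.all(np.isfinite(C))
        np.testing.assert_allclose(Qs.Q.sum(), 1.0)
        np.testing.assert_allclose(Qs.Q[0, 1], 1 / 104)


class TestSinkhorn:
    def test_q_marginals_give_zero_cost(self):
        rng = np.random.default_rng(0)
        Qm = rng.dirichlet(np.ones(16)).reshape(4, 4)
        Q = _jq(Qm)
        sol = _solve(Qm, Q.row_marginal(), Q.col_marginal())
        assert sol.cost == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(sol.P, Qm, atol=1e-9)

    def test_k2_matches_one_dimensional_minimization(self):
        """With K = 2 the polytope has one free parameter P_00; a bounded
        scalar minimization is an independent oracle."""
        Qm = np.array([[0.4, 0.1], [0.2, 0.3]])
        pi0, piT = np.array([0.5, 0.5]), np.array([0.7, 0.3])

        def cost_of(p00):
            P = np.array([[p00, pi0[0] - p00],
                          [piT[0] - p00, pi0[1] - piT[0] + p00]])
            return plan_kl(np.clip(P, 0, None), Qm)

        lo = max(0.0, piT[0] - pi0[1])
        hi = min(pi0[0], piT[0])
        res = minimize_scalar(cost_of, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        sol = _solve(Qm, pi0, piT)
        assert sol.cost == pytest.approx(res.fun, abs=1e-4)

    def test_uniform_q_closed_form(self):
        """For independent uniform Q the optimal plan is the outer product,
        so cost = KL(pi0||u) + KL(piT||u)."""
        rng = np.random.default_rng(1)
        for K in (2, 3):
            u = np.full(K, 1 / K)
            Qm = np.full((K, K), 1 / K**2)
            pi0, piT = rng.dirichlet(np.ones(K)), rng.dirichlet(np.ones(K))
            sol = _solve(Qm, pi0, piT)
            expected = kl_divergence(pi0, u) + kl_divergence(piT, u)
            assert sol.cost == pytest.approx(expected, abs=1e-8)
            np.testing.assert_allclose(sol.P, np.outer(pi0, piT), atol=1e-8)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            K = rng.integers(2, 4)
            Qm = rng.dirichlet(np.ones(K * K)).reshape(K, K)
            pi0, piT = rng.dirichlet(np.ones(K)), rng.dirichlet(np.ones(K))
            sol = _solve(Qm, pi0, piT)
            assert sol.cost == pytest.approx(
                bridge_cost_bruteforce(Qm, pi0, piT), abs=1e-4
            )

    def test_objective_decomposition_identity(self):
        """sum C_ij P_ij - H(P) equals D_KL(P||Q) on every solve."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            Qm = rng.dirichlet(np.ones(9)).reshape(3, 3)
            pi0, piT = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
            prob = TransportProblem.from_distributions(_jq(Qm), pi0, piT)
            sol = sinkhorn_bridge(prob)
            P = sol.P
            H = -np.sum(P[P > 0] * np.log(P[P > 0]))
            assert np.sum(prob.C * P) - H == pytest.approx(sol.cost, abs=1e-10)

    def test_marginals_satisfied_and_plan_normalized(self):
        rng = np.random.default_rng(4)
        Qm = rng.dirichlet(np.ones(25)).reshape(5, 5)
        pi0, piT = rng.dirichlet(np.ones(5)), rng.dirichlet(np.ones(5))
        sol = _solve(Qm, pi0, piT, tol=1e-12)
        np.testing.assert_allclose(sol.P.sum(axis=1), pi0, atol=1e-11)
        np.testing.assert_allclose(sol.P.sum(axis=0), piT, atol=1e-11)
        assert sol.P.sum() == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_multiplier_rescaling(self):
        """diag(u) Q diag(v) is unchanged by u -> c u, v -> v / c; the solver
        must land on the same plan from any starting scale."""
        Qm = np.array([[0.4, 0.1], [0.2, 0.3]])
        a = _solve(Qm, [0.5, 0.5], [0.7, 0.3])
        b = _solve(100 * Qm / (100 * Qm).sum(), [0.5, 0.5], [0.7, 0.3])
        assert a.cost == pytest.approx(b.cost, abs=1e-8)

    def test_zero_support_infeasible(self):
        Qm = np.array([[0.5, 0.0], [0.0, 0.5]])
        Qm2 = np.array([[0.5, 0.5], [0.0, 0.0]])
        with pytest.raises(InfeasibleMarginalsError, match="pseudocount"):
            _solve(Qm2.T, [0.5, 0.5], [0.5, 0.5])

    def test_sparse_q_solvable_with_pseudocount(self):
        Q = _jq([[0.5, 0.5], [0.0, 0.0]], n_pairs=10)
        prob = TransportProblem.from_distributions(
            Q, [0.5, 0.5], [0.5, 0.5], pseudocount=1.0
        )
        sol = sinkhorn_bridge(prob)
        assert np.isfinite(sol.cost)

    def test_convexity_along_target_segment(self):
        """cost(piT) is convex: at the midpoint it lies below the chord."""
        rng = np.random.default_rng(5)
        Qm = rng.dirichlet(np.ones(9)).reshape(3, 3)
        pi0 = rng.dirichlet(np.ones(3))
        a, b = rng.dirichlet(np.ones(3)), rng.dirichlet(np.ones(3))
        mid = 0.5 * (a + b)
        c_mid = _solve(Qm, pi0, mid).cost
        chord = 0.5 * (_solve(Qm, pi0, a).cost + _solve(Qm, pi0, b).cost)
        assert c_mid <= chord + 1e-9


class TestPerCondition:
    def _cov(self, pi, cond):
        return CoverageDistribution(pi=np.asarray(pi), condition=cond, n_samples=100)

    def test_rest_equal_task_zero_cost(self):
        rng = np.random.default_rng(6)
        Qm = rng.dirichlet(np.ones(9)).reshape(3, 3)
        Q = _jq(Qm)
        table = transition_cost_per_condition(
            Q, Q.row_marginal(),
            [self._cov(Q.col_marginal(), "same")],
        )
        assert table.loc[0, "cost"] == pytest.approx(0.0, abs=1e-10)

    def test_farther_target_costs_more_along_ray(self):
        """Cost grows monotonically moving the target away from the
        zero-cost point along a fixed direction (convexity from the
        minimizer)."""
        rng = np.random.default_rng(7)
        Qm = rng.dirichlet(np.ones(9)).reshape(3, 3)
        Q = _jq(Qm)
        base = Q.col_marginal()
        direction = np.array([0.3, -0.1, -0.2])
        pis = [self._cov(base + s * direction, f"s{i}")
               for i, s in enumerate([0.2, 0.5, 0.8])]
        table = transition_cost_per_condition(Q, Q.row_marginal(), pis)
        costs = table.sort_values("condition")["cost"].to_numpy()
        assert np.all(np.diff(costs) > 0)

    def test_sorted_by_condition(self):
        rng = np.random.default_rng(8)
        Qm = rng.dirichlet(np.ones(4)).reshape(2, 2)
        Q = _jq(Qm)
        pis = [self._cov(rng.dirichlet(np.ones(2)), c) for c in ("b", "a")]
        table = transition_cost_per_condition(Q, Q.row_marginal(), pis)
        assert table["condition"].tolist() == ["a", "b"]


class TestKLDivergence:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0.3, 0.7], [0.3, 0.7], 0.0),
            ([0.5, 0.5], [0.75, 0.25], 0.14384),
            ([1.0, 0.0], [0.5, 0.5], np.log(2)),
        ],
    )
    def test_hand_values(self, a, b, expected):
        assert kl_divergence(a, b) == pytest.approx(expected, abs=1e-5)

    def test_support_violation_raises(self):
        with pytest.raises(SupportViolationError):
            kl_divergence([0.5, 0.5], [1.0, 0.0])

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b = rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4))
            assert kl_divergence(a, b) >= 0.0
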