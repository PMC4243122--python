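import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hubernet import (
    GroupCoefficients,
    SolverConfig,
    gamma_bound,
    huber_grad,
    huber_loss,
    kkt_check,
    lambda_max,
    solve_path,
    solve_target,
)
from hubernet.solver import block_gamma_bounds, block_update, objective

from conftest import make_random_problem


# ---------------------------------------------------------------- oracles

def fista_oracle(problem, lam, delta, n_iter=50_000, tol=1e-13):
    """Accelerated proximal-gradient reference solver for the same objective."""
    X, y, w = problem.design, problem.y, problem.obs_weights
    p, m = problem.n_groups, problem.group_size
    L = 2.0 * gamma_bound(problem)
    b = np.zeros(p * m)
    z = b.copy()
    tk = 1.0
    for _ in range(n_iter):
        r = y - X @ z
        g = -(X.T @ (w * huber_grad(r, delta)))
        u = (z - g / L).reshape(p, m)
        norms = np.linalg.norm(u, axis=1)
        shrink = np.maximum(0.0, 1.0 - (lam / L) / np.where(norms > 0, norms, 1.0))
        b_new = (u * shrink[:, None]).reshape(-1)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
        z = b_new + ((tk - 1.0) / t_new) * (b_new - b)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b, tk = b_new, t_new
    return GroupCoefficients.from_flat(b, p, m)


def power_iteration_top_eig(M, n_iter=2000):
    v = np.ones(M.shape[0]) / np.sqrt(M.shape[0])
    for _ in range(n_iter):
        v = M @ v
        v /= np.linalg.norm(v)
    return float(v @ M @ v)


# ---------------------------------------------------------------- loss

class TestHuberLoss:
    @pytest.mark.parametrize(
        "theta,delta,expected",
        [(0.0, 1.0, 0.0), (1.0, 1.0, 1.0), (3.0, 1.0, 5.0), (-3.0, 1.0, 5.0)],
    )
    def test_values(self, theta, delta, expected):
        assert huber_loss(theta, delta) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "theta,delta,expected", [(0.5, 1.0, 1.0), (-3.0, 1.0, -2.0), (0.0, 2.0, 0.0)]
    )
    def test_gradient_values(self, theta, delta, expected):
        assert huber_grad(theta, delta) == pytest.approx(expected)

    @given(
        theta=st.floats(-50, 50),
        delta=st.floats(0.01, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_continuity_at_transition_and_bounded_gradient(self, theta, delta):
        # both branches agree at |theta| = delta
        assert huber_loss(delta, delta) == pytest.approx(delta**2, rel=1e-12)
        assert abs(huber_grad(theta, delta)) <= 2 * delta + 1e-12

    @given(
        t1=st.floats(-30, 30),
        t2=st.floats(-30, 30),
        delta=st.floats(0.01, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_gradient_is_monotone_and_2_lipschitz(self, t1, t2, delta):
        lhs = (huber_grad(t1, delta) - huber_grad(t2, delta)) * (t1 - t2)
        assert 0 <= lhs <= 2 * (t1 - t2) ** 2 + 1e-9


# ---------------------------------------------------------------- curvature

class TestGammaBound:
    def test_rank_one_design(self):
        prob = make_random_problem(m=1, p=2, n_obs=1, seed=0)
        x = prob.design[0]
        prob_gamma = gamma_bound(prob)
        assert prob_gamma == pytest.approx(prob.obs_weights[0] * x @ x)

    def test_matches_power_iteration(self):
        prob = make_random_problem(m=3, p=5, n_obs=12, seed=3)
        gram = prob.design.T @ (prob.design * prob.obs_weights[:, None])
        assert gamma_bound(prob) == pytest.approx(
            power_iteration_top_eig(gram), abs=1e-8
        )

    def test_block_bounds_dominated_by_global(self):
        prob = make_random_problem(m=2, p=4, n_obs=10, seed=5)
        blocks = block_gamma_bounds(prob)
        assert np.all(blocks <= gamma_bound(prob) + 1e-12)
        assert np.all(blocks > 0)


# ---------------------------------------------------------------- block update

class TestBlockUpdate:
    def _majorizer_restricted(self, prob, coef, block, lam, delta, gamma):
        """Q of the MM construction as a function of one block."""
        flat0 = coef.flat
        r0 = prob.y - prob.design @ flat0
        f0 = float(np.dot(prob.obs_weights, huber_loss(r0, delta)))
        grad = -(prob.design.T @ (prob.obs_weights * huber_grad(r0, delta)))
        cols = prob.group_slice(block)

        def q(bl):
            d = np.zeros_like(flat0)
            d[cols] = bl - flat0[cols]
            return (
                f0
                + grad @ d
                + 2.0 * gamma * float(d @ d)
                + lam * float(np.linalg.norm(bl))
            )

        return q

    def test_zero_when_threshold_dominates(self):
        prob = make_random_problem(seed=7)
        gamma = gamma_bound(prob)
        coef = GroupCoefficients(np.zeros((prob.n_groups, prob.group_size)))
        huge_lam = 1e9
        out = block_update(prob, coef, 0, huge_lam, 1.0, gamma)
        np.testing.assert_array_equal(out, 0.0)

    def test_unpenalized_step_is_scaled_gradient(self):
        prob = make_random_problem(seed=8)
        gamma = gamma_bound(prob)
        coef = GroupCoefficients(np.zeros((prob.n_groups, prob.group_size)))
        out = block_update(prob, coef, 1, 0.0, 2.0, gamma)
        cols = prob.group_slice(1)
        g = prob.design[:, cols].T @ (
            prob.obs_weights * huber_grad(prob.y, 2.0)
        )
        np.testing.assert_allclose(out, g / (4 * gamma), rtol=1e-12)

    @pytest.mark.parametrize("block", [0, 1])
    def test_matches_numerical_minimizer_of_majorizer(self, block):
        from scipy.optimize import minimize

        prob = make_random_problem(m=2, p=2, n_obs=12, seed=9)
        gamma = gamma_bound(prob)
        rng = np.random.default_rng(3)
        coef = GroupCoefficients(rng.normal(size=(2, 2)))
        lam, delta = 0.7, 1.5
        q = self._majorizer_restricted(prob, coef, block, lam, delta, gamma)
        best = None
        for start in [np.zeros(2), coef.groups[block], rng.normal(size=2)]:
            res = minimize(q, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14,
                                    "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        out = block_update(prob, coef, block, lam, delta, gamma)
        assert q(out) <= best.fun + 1e-10
        np.testing.assert_allclose(out, best.x, atol=1e-6)


# ---------------------------------------------------------------- solve

class TestSolveTarget:
    def test_unpenalized_single_predictor_matches_least_squares(self):
        prob = make_random_problem(m=1, p=1, n_obs=20, seed=11)
        big_delta = 1e6  # all residuals quadratic
        res = solve_target(prob, SolverConfig(delta=big_delta, lam=0.0, tol=1e-10))
        X, y, w = prob.design, prob.y, prob.obs_weights
        expected = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        np.testing.assert_allclose(res.coefficients.flat, expected, atol=1e-6)

    def test_objective_history_is_monotone_decreasing(self):
        prob = make_random_problem(m=3, p=4, n_obs=12, seed=13)
        for loss in ("huber", "squared"):
            res = solve_target(
                prob,
                SolverConfig(delta=1.0, lam=0.5, loss=loss),
                track_objective=True,
            )
            hist = res.objective_history
            assert hist is not None and len(hist) == res.n_iterations + 1
            assert np.all(np.diff(hist) <= 1e-12)

    def test_global_and_block_curvature_reach_same_optimum(self):
        prob = make_random_problem(m=2, p=3, n_obs=15, seed=17)
        lam = 0.3 * lambda_max(prob, 1.0)
        a = solve_target(prob, SolverConfig(delta=1.0, lam=lam, tol=1e-9,
                                            gamma_mode="block"))
        b = solve_target(prob, SolverConfig(delta=1.0, lam=lam, tol=1e-9,
                                            gamma_mode="global"))
        assert a.objective == pytest.approx(b.objective, rel=1e-7)

    def test_python_block_updates_reproduce_kernel_solution(self):
        prob = make_random_problem(m=2, p=3, n_obs=10, seed=19)
        lam, delta = 0.4, 1.2
        gamma = gamma_bound(prob)
        coef = GroupCoefficients(np.zeros((3, 2)))
        for _ in range(4000):
            groups = coef.groups.copy()
            for l in range(3):
                groups[l] = block_update(
                    prob, GroupCoefficients(groups), l, lam, delta, gamma
                )
            coef = GroupCoefficients(groups)
        res = solve_target(prob, SolverConfig(delta=delta, lam=lam, tol=1e-10),
                           gamma=gamma)
        np.testing.assert_allclose(coef.flat, res.coefficients.flat, atol=1e-6)

    def test_huber_equals_squared_when_delta_exceeds_all_residuals(self):
        prob = make_random_problem(m=2, p=4, n_obs=12, seed=23)
        lam = 0.2 * lambda_max(prob, np.inf)
        sq = solve_target(prob, SolverConfig(lam=lam, loss="squared", tol=1e-9))
        hb = solve_target(
            prob, SolverConfig(delta=1e8, lam=lam, loss="huber", tol=1e-9)
        )
        np.testing.assert_allclose(
            hb.coefficients.flat, sq.coefficients.flat, atol=1e-6
        )

    def test_support_recovery_on_noise_free_simulation(self, template):
        from hubernet import (
            DatasetFamily,
            SimulationConfig,
            assemble_target,
            generate_network_family,
            simulate_timecourse,
        )

        rng = np.random.default_rng(29)
        networks = generate_network_family(template, 2, rng)
        cfg = SimulationConfig(m=2, n_obs=12, contamination_prob=0.0,
                               sd_small=1e-300)
        family = DatasetFamily(
            [simulate_timecourse(net, cfg, rng, dataset_id=f"d{k}")
             for k, net in enumerate(networks)]
        )
        for i in range(template.p):
            prob = assemble_target(family, i)
            lam = 1e-4 * lambda_max(prob, np.inf)
            res = solve_target(prob, SolverConfig(lam=lam, loss="squared",
                                                  tol=1e-10))
            recovered = set(np.flatnonzero(res.coefficients.support(1e-6)))
            true = set(np.flatnonzero(template.signs[i] != 0))
            assert true <= recovered


# ---------------------------------------------------------------- lambda_max

class TestLambdaMax:
    def test_zero_response_gives_zero(self):
        prob = make_random_problem(seed=31)
        object.__setattr__(prob, "y", np.zeros_like(prob.y))
        assert lambda_max(prob, 1.0) == 0.0

    @pytest.mark.parametrize("loss,delta", [("huber", 1.3), ("squared", np.inf)])
    def test_empty_network_at_and_above_threshold(self, loss, delta):
        prob = make_random_problem(m=2, p=4, n_obs=10, seed=37)
        lmax = lambda_max(prob, delta)
        cfg = SolverConfig(delta=1.3 if loss == "huber" else 1.0,
                           lam=1.001 * lmax, loss=loss)
        res = solve_target(prob, cfg)
        np.testing.assert_array_equal(res.coefficients.flat, 0.0)

    def test_matches_brute_force_group_gradient_norms(self):
        prob = make_random_problem(m=3, p=4, n_obs=9, seed=41)
        delta = 0.9
        norms = []
        for l in range(prob.n_groups):
            acc = np.zeros(prob.group_size)
            for j in range(prob.n):
                acc += (
                    prob.obs_weights[j]
                    * huber_grad(prob.y[j], delta)
                    * prob.design[j, prob.group_slice(l)]
                )
            norms.append(np.linalg.norm(acc))
        assert lambda_max(prob, delta) == pytest.approx(max(norms), abs=1e-10)


# ---------------------------------------------------------------- path

class TestSolutionPath:
    def test_grid_endpoints(self):
        prob = make_random_problem(seed=43)
        path = solve_path(prob, delta=1.0, n_lambdas=2, lam_min_ratio=0.01)
        lmax = lambda_max(prob, 1.0)
        np.testing.assert_allclose(path.lambdas, [lmax, 0.01 * lmax])

    def test_first_solution_is_empty_and_support_grows(self):
        prob = make_random_problem(m=2, p=5, n_obs=14, seed=47)
        path = solve_path(prob, delta=1.0, n_lambdas=12)
        counts = [int(s.coefficients.support(1e-8).sum()) for s in path.solutions]
        assert counts[0] == 0
        assert counts[-1] >= counts[0]
        assert np.all(np.diff(counts) >= 0)

    def test_final_objective_below_empty_model(self):
        prob = make_random_problem(seed=53)
        path = solve_path(prob, delta=1.0, n_lambdas=8)
        assert path.solutions[-1].objective < path.solutions[0].objective


# ---------------------------------------------------------------- KKT

class TestKKT:
    def test_origin_optimal_for_zero_data(self):
        prob = make_random_problem(seed=59)
        object.__setattr__(prob, "y", np.zeros_like(prob.y))
        coef = GroupCoefficients(
            np.zeros((prob.n_groups, prob.group_size))
        )
        assert kkt_check(prob, coef, 1.0, 1.0) == 0.0

    def test_converged_solution_is_stationary(self):
        prob = make_random_problem(m=2, p=4, n_obs=20, seed=61)
        lam = 0.3 * lambda_max(prob, 1.0)
        res = solve_target(prob, SolverConfig(delta=1.0, lam=lam, tol=1e-8))
        assert res.kkt_violation < 1e-4

    def test_perturbation_increases_violation(self):
        prob = make_random_problem(m=2, p=3, n_obs=15, seed=67)
        lam = 0.2 * lambda_max(prob, 1.0)
        res = solve_target(prob, SolverConfig(delta=1.0, lam=lam, tol=1e-9))
        base = res.kkt_violation
        bumped = res.coefficients.groups.copy()
        bumped[0] += 0.5
        worse = kkt_check(prob, GroupCoefficients(bumped), lam, 1.0)
        assert worse > base


# ---------------------------------------------------------------- majorization

def test_majorizer_dominates_objective_on_random_pairs():
    """Q(b'|b) >= J(b') with equality Q(b|b) = J(b), using the global bound."""
    prob = make_random_problem(m=2, p=3, n_obs=12, seed=71)
    gamma = gamma_bound(prob)
    lam, delta = 0.8, 1.1
    rng = np.random.default_rng(5)
    X, y, w = prob.design, prob.y, prob.obs_weights

    def J(flat):
        coef = GroupCoefficients.from_flat(flat, 3, 2)
        return objective(prob, coef, lam, delta)

    def Q(flat_new, flat_at):
        r = y - X @ flat_at
        f_at = float(np.dot(w, huber_loss(r, delta)))
        grad = -(X.T @ (w * huber_grad(r, delta)))
        d = flat_new - flat_at
        pen = lam * float(
            np.linalg.norm(flat_new.reshape(3, 2), axis=1).sum()
        )
        return f_at + grad @ d + 2.0 * gamma * float(d @ d) + pen

    for _ in range(120):
        b_at = rng.normal(scale=2.0, size=6)
        b_new = rng.normal(scale=2.0, size=6)
        assert Q(b_new, b_at) >= J(b_new) - 1e-10
        assert Q(b_at, b_at) == pytest.approx(J(b_at), abs=1e-10)


def test_solution_matches_accelerated_proximal_oracle():
    """MM block descent and FISTA agree on objective value and support."""
    for seed in (0, 1, 2):
        prob = make_random_problem(m=2, p=4, n_obs=16, seed=seed)
        delta = 1.2
        lam = 0.25 * lambda_max(prob, delta)
        res = solve_target(prob, SolverConfig(delta=delta, lam=lam, tol=1e-9))
        oracle = fista_oracle(prob, lam, delta)
        j_mm = objective(prob, res.coefficients, lam, delta)
        j_or = objective(prob, oracle, lam, delta)
        assert abs(j_mm - j_or) <= 1e-5 * max(1.0, abs(j_or))
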