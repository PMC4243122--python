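"""Huber group LASSO solver for one target gene's stacked regression.

The objective over the grouped coefficient vector ``b`` (p groups of m
per-dataset copies) is

    J(b) = sum_j w_j H_d(y_j - x_j^T b) + lam * sum_l ||b_l||_2

where ``H_d`` is the Huber loss (quadratic within ``+-delta``, linear
outside) or, for the plain group LASSO, the squared error.  Minimization is
by cyclic block-coordinate descent on a quadratic majorizer: at the current
iterate the smooth loss is replaced by

    Q(b | b') = f(b') + grad f(b')^T (b - b') + 2*gamma*||b - b'||^2 + penalty,

with ``gamma`` the largest eigenvalue of the weighted Gram matrix
``sum_j w_j x_j x_j^T``.  Because the Huber gradient is 2-Lipschitz along
the design, Q majorizes J, and its exact per-block minimizer is a group
soft-threshold — so every cycle decreases J and the iterates converge to
the global minimum of this convex problem.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import path_kernel, solve_kernel
from .assembly import GroupCoefficients, TargetRegression

__all__ = [
    "SolverConfig",
    "SolveResult",
    "SolutionPath",
    "huber_loss",
    "huber_grad",
    "objective",
    "gamma_bound",
    "block_gamma_bounds",
    "block_update",
    "solve_target",
    "lambda_max",
    "solve_path",
    "kkt_check",
]


@dataclass(frozen=True)
class SolverConfig:
    """Penalty, robustness transition point, loss and stopping rules."""

    delta: float = 1.0
    lam: float = 0.0
    tol: float = 1e-6
    max_iter: int = 10_000
    loss: str = "huber"  # "huber" | "squared"
    gamma_mode: str = "block"  # "block" | "global"

    def __post_init__(self) -> None:
        if self.loss not in ("huber", "squared"):
            raise ValueError("loss must be 'huber' or 'squared'")
        if self.gamma_mode not in ("block", "global"):
            raise ValueError("gamma_mode must be 'block' or 'global'")
        if self.loss == "huber" and not self.delta > 0:
            raise ValueError("delta must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    @property
    def effective_delta(self) -> float:
        """Squared error is the delta -> inf limit of the Huber loss."""
        return np.inf if self.loss == "squared" else self.delta


@dataclass(frozen=True)
class SolveResult:
    coefficients: GroupCoefficients
    objective: float
    n_iterations: int
    converged: bool
    kkt_violation: float
    objective_history: np.ndarray | None = None


@dataclass(frozen=True)
class SolutionPath:
    lambdas: np.ndarray
    solutions: tuple[SolveResult, ...]


def huber_loss(theta, delta: float):
    """theta^2 inside +-delta, 2*delta*|theta| - delta^2 outside."""
    theta = np.asarray(theta, dtype=float)
    if np.isinf(delta):  # squared-error limit
        return theta * theta
    a = np.abs(theta)
    return np.where(a <= delta, theta * theta, 2.0 * delta * a - delta * delta)


def huber_grad(theta, delta: float):
    """Derivative of the Huber loss: 2*theta clipped to +-2*delta."""
    theta = np.asarray(theta, dtype=float)
    return np.clip(2.0 * theta, -2.0 * delta, 2.0 * delta)


def objective(
    problem: TargetRegression, coefficients: GroupCoefficients, lam: float, delta: float
) -> float:
    """J(b): weighted Huber data fit plus the group L2 penalty."""
    r = problem.y - problem.design @ coefficients.flat
    fit = float(np.dot(problem.obs_weights, huber_loss(r, delta)))
    return fit + lam * float(coefficients.group_norms().sum())


def gamma_bound(problem: TargetRegression) -> float:
    """Largest eigenvalue of the weighted Gram matrix sum_j w_j x_j x_j^T."""
    Xw = problem.design * problem.obs_weights[:, None]
    gram = problem.design.T @ Xw
    gamma = float(np.linalg.eigvalsh(gram)[-1])
    if gamma <= 0.0:
        raise ValueError("design is all-zero; majorizer curvature undefined")
    return gamma


def block_gamma_bounds(problem: TargetRegression) -> np.ndarray:
    """Per-block majorizer curvatures: top eigenvalue of each block's Gram.

    Because one block is updated at a time, the quadratic term of the
    majorizer only needs to dominate the loss curvature along that block,
    which the largest eigenvalue of sum_j w_j x_{j,l} x_{j,l}^T does; it is
    far smaller than the global bound when predictors are correlated across
    blocks, and proportionally larger steps make the Huber solves practical.
    All-zero blocks fall back to the global bound (their update is zero
    regardless).
    """
    global_gamma = gamma_bound(problem)
    gammas = np.empty(problem.n_groups)
    for l in range(problem.n_groups):
        cols = problem.group_slice(l)
        Xl = problem.design[:, cols]
        gram = Xl.T @ (Xl * problem.obs_weights[:, None])
        gammas[l] = float(np.linalg.eigvalsh(gram)[-1])
        if gammas[l] <= 0.0:
            gammas[l] = global_gamma
    return gammas


def _resolve_gammas(
    problem: TargetRegression, config: "SolverConfig", gamma
) -> np.ndarray:
    if gamma is not None:
        return np.full(problem.n_groups, float(gamma))
    if config.gamma_mode == "global":
        return np.full(problem.n_groups, gamma_bound(problem))
    return block_gamma_bounds(problem)


def block_update(
    problem: TargetRegression,
    b_current: GroupCoefficients,
    block: int,
    lam: float,
    delta: float,
    gamma: float,
) -> np.ndarray:
    """Exact minimizer of the majorizer Q over one group (soft-threshold).

    v = sum_j w_j H'_d(y_j - x_j^T b) x_{j,block} + 4*gamma*b_block, then
    the new block is (1/(4*gamma)) * (1 - lam/||v||)_+ * v.
    """
    flat = b_current.flat
    r = problem.y - problem.design @ flat
    cols = problem.group_slice(block)
    g = problem.design[:, cols].T @ (problem.obs_weights * huber_grad(r, delta))
    v = g + 4.0 * gamma * flat[cols]
    vnorm = float(np.linalg.norm(v))
    if vnorm == 0.0 or vnorm <= lam:
        return np.zeros_like(v)
    return (1.0 - lam / vnorm) / (4.0 * gamma) * v


def solve_target(
    problem: TargetRegression,
    config: SolverConfig,
    warm_start: GroupCoefficients | None = None,
    gamma: float | None = None,
    track_objective: bool = False,
) -> SolveResult:
    """Cycle block updates until the largest coefficient change drops below tol."""
    p, m = problem.n_groups, problem.group_size
    gammas = _resolve_gammas(problem, config, gamma)
    b0 = np.zeros(p * m) if warm_start is None else warm_start.flat.copy()
    delta = config.effective_delta
    b, n_iter, converged, hist = solve_kernel(
        np.ascontiguousarray(problem.design.T),
        problem.y,
        problem.obs_weights,
        p,
        m,
        float(config.lam),
        delta,
        gammas,
        config.tol,
        config.max_iter,
        b0,
        track_objective,
    )
    coefficients = GroupCoefficients.from_flat(b, p, m)
    return SolveResult(
        coefficients=coefficients,
        objective=objective(problem, coefficients, config.lam, delta),
        n_iterations=int(n_iter),
        converged=bool(converged),
        kkt_violation=kkt_check(problem, coefficients, config.lam, delta),
        objective_history=hist if track_objective else None,
    )


def lambda_max(problem: TargetRegression, delta: float) -> float:
    """Smallest penalty at which the all-zero solution is optimal.

    Equals the largest group norm of the loss gradient at b = 0:
    max_l || sum_j w_j H'_d(y_j) x_{j,l} ||_2.
    """
    g = problem.design.T @ (problem.obs_weights * huber_grad(problem.y, delta))
    norms = np.linalg.norm(g.reshape(problem.n_groups, problem.group_size), axis=1)
    return float(norms.max())


def lambda_grid(lam_max: float, n_lambdas: int, lam_min_ratio: float) -> np.ndarray:
    """Logarithmic grid from lam_max down to lam_min_ratio * lam_max."""
    if n_lambdas < 2:
        raise ValueError("n_lambdas must be >= 2")
    if not 0.0 < lam_min_ratio < 1.0:
        raise ValueError("lam_min_ratio must be in (0, 1)")
    if lam_max <= 0.0:
        return np.zeros(n_lambdas)
    return np.geomspace(lam_max, lam_min_ratio * lam_max, n_lambdas)


def solve_path(
    problem: TargetRegression,
    delta: float | None = None,
    n_lambdas: int = 20,
    lam_min_ratio: float = 0.01,
    config: SolverConfig | None = None,
    lambdas: np.ndarray | None = None,
    gamma: float | None = None,
) -> SolutionPath:
    """Warm-started solves along a decreasing penalty grid.

    The grid runs from this problem's lambda_max (all groups zero) down to
    ``lam_min_ratio * lambda_max``; an explicit ``lambdas`` overrides it.
    """
    if config is None:
        config = SolverConfig(delta=delta if delta is not None else 1.0)
    if delta is not None and config.loss == "huber":
        config = replace(config, delta=delta)
    eff_delta = config.effective_delta
    gammas = _resolve_gammas(problem, config, gamma)
    if lambdas is None:
        lambdas = lambda_grid(lambda_max(problem, eff_delta), n_lambdas, lam_min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    p, m = problem.n_groups, problem.group_size
    B, iters, conv = path_kernel(
        np.ascontiguousarray(problem.design.T),
        problem.y,
        problem.obs_weights,
        p,
        m,
        lambdas,
        eff_delta,
        gammas,
        config.tol,
        config.max_iter,
    )
    solutions = []
    for i, lam in enumerate(lambdas):
        coefficients = GroupCoefficients.from_flat(B[i], p, m)
        solutions.append(
            SolveResult(
                coefficients=coefficients,
                objective=objective(problem, coefficients, lam, eff_delta),
                n_iterations=int(iters[i]),
                converged=bool(conv[i]),
                kkt_violation=kkt_check(problem, coefficients, lam, eff_delta),
            )
        )
    return SolutionPath(lambdas=lambdas, solutions=tuple(solutions))


def kkt_check(
    problem: TargetRegression,
    coefficients: GroupCoefficients,
    lam: float,
    delta: float,
) -> float:
    """Max group-wise violation of the first-order optimality conditions.

    Nonzero groups must satisfy grad_l f + lam * b_l/||b_l|| = 0; zero groups
    must have ||grad_l f|| <= lam.
    """
    flat = coefficients.flat
    r = problem.y - problem.design @ flat
    grad = -(problem.design.T @ (problem.obs_weights * huber_grad(r, delta)))
    grad = grad.reshape(problem.n_groups, problem.group_size)
    groups = coefficients.groups
    norms = np.linalg.norm(groups, axis=1)
    worst = 0.0
    for l in range(problem.n_groups):
        if norms[l] > 0:
            viol = float(np.linalg.norm(grad[l] + lam * groups[l] / norms[l]))
        else:
            viol = max(0.0, float(np.linalg.norm(grad[l])) - lam)
        worst = max(worst, viol)
    return worst
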