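"""Data-driven choice of the Huber transition point delta.

The transition point separates residuals treated quadratically (ordinary
least-squares behaviour) from those treated linearly (bounded influence).
It is set per target gene to

    delta = max(1.345 * sigma_hat, 1),      sigma_hat = AD / 0.6745,

where AD is an absolute-deviation summary of least-absolute-deviations
(LAD) regression residuals and 1.345 is the classical 95%-efficiency
tuning; the floor of 1 guards against an overfit LAD whose residuals would
otherwise drive delta toward zero.

The LAD pre-fit regresses the target gene's responses on the lagged
expression vector with a single coefficient vector shared by all datasets
(the pooled autoregression).  With only p parameters this fit cannot chase
noise the way the full per-dataset parameterization can — the overfitting
the floor worries about — and its residuals retain the across-dataset
variation in regulatory strength, so sigma_hat reflects the spread of
residuals the grouped solver actually encounters while supports are still
being resolved.  The deviation summary is the mean absolute deviation about
the residual median: unlike the median deviation it responds to the heavy
contaminated tail, which widens delta just enough to keep the bulk of
informative observations in the quadratic regime while gross errors stay
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .assembly import DatasetFamily, TargetRegression

__all__ = [
    "ScaleEstimate",
    "lad_residuals",
    "pooled_lad_residuals",
    "estimate_delta",
    "delta_for_target",
]

MAD_CONSISTENCY = 0.6745  # median absolute deviation of N(0, 1)
HUBER_EFFICIENCY = 1.345  # 95% efficiency at the Gaussian


@dataclass(frozen=True)
class ScaleEstimate:
    sigma_hat: float
    mad: float  # the absolute-deviation summary actually used
    delta: float


class LADError(RuntimeError):
    """The LAD linear program failed to terminate at an optimum."""


def _lad_linprog(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Exact weighted LAD via LP: min sum_j w_j t_j, t_j >= |y_j - x_j b|."""
    n, d = X.shape
    c = np.concatenate([np.zeros(d), w])
    eye = np.eye(n)
    A_ub = np.block([[X, -eye], [-X, -eye]])
    b_ub = np.concatenate([y, -y])
    bounds = [(None, None)] * d + [(0, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise LADError(f"LAD linear program failed: {res.message}")
    return res.x[:d]


def _lad_irls(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, ridge: float,
    max_iter: int = 200, tol: float = 1e-10,
) -> np.ndarray:
    """Ridge-guarded LAD by iteratively reweighted least squares.

    Used when the design is column-rank-deficient, where the plain LAD
    program is ill-posed; the tiny quadratic term makes the minimizer
    unique while the floor on delta absorbs the small distortion.
    """
    d = X.shape[1]
    b = np.zeros(d)
    reg = ridge * np.eye(d)
    for _ in range(max_iter):
        r = y - X @ b
        dweights = w / np.maximum(np.abs(r), 1e-8)
        XtW = X.T * dweights
        b_new = np.linalg.solve(XtW @ X + reg, XtW @ y)
        if np.max(np.abs(b_new - b)) < tol:
            b = b_new
            break
        b = b_new
    return b


def _lad_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    if X.shape[0] > X.shape[1] and np.linalg.matrix_rank(X) == X.shape[1]:
        return _lad_linprog(X, y, w)
    gram_top = float(
        np.linalg.eigvalsh(X.T @ (X * w[:, None]))[-1]
    )
    return _lad_irls(X, y, w, ridge=1e-6 * max(gram_top, 1e-12))


def lad_residuals(problem: TargetRegression) -> np.ndarray:
    """Residuals of the weighted LAD fit of the full stacked target problem.

    Uses the grouped per-dataset design (p*m coefficients); with generous
    data this fit interpolates much of the noise, which is why the delta
    rule prefers :func:`pooled_lad_residuals`.
    """
    b = _lad_fit(problem.design, problem.y, problem.obs_weights)
    return problem.y - problem.design @ b


def pooled_lad_residuals(family: DatasetFamily, target_index: int) -> np.ndarray:
    """Weighted LAD residuals of the pooled (shared-coefficient) autoregression.

    One coefficient per regulator gene, common to all datasets: the
    parsimonious pre-fit whose residuals calibrate delta.
    """
    X = np.concatenate(
        [s.predecessors for s in family.datasets], axis=1
    ).T  # n x p
    y = np.concatenate([s.successors[target_index] for s in family.datasets])
    w = np.concatenate(
        [
            np.full(s.n_transitions, wk)
            for s, wk in zip(family.datasets, family.weights)
        ]
    )
    b = _lad_fit(X, y, w)
    return y - X @ b


def estimate_delta(residuals: np.ndarray, scale: str = "mean") -> ScaleEstimate:
    """Absolute-deviation scale of the residuals and the floored transition point.

    ``scale`` selects the deviation summary about the residual median:
    ``"mean"`` (default; tail-sensitive) or ``"median"`` (the classical MAD).
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 1:
        raise ValueError("need at least one residual")
    if scale not in ("mean", "median"):
        raise ValueError("scale must be 'mean' or 'median'")
    dev = np.abs(residuals - np.median(residuals))
    ad = float(np.mean(dev) if scale == "mean" else np.median(dev))
    sigma_hat = ad / MAD_CONSISTENCY
    return ScaleEstimate(
        sigma_hat=sigma_hat,
        mad=ad,
        delta=max(HUBER_EFFICIENCY * sigma_hat, 1.0),
    )


def delta_for_target(family: DatasetFamily, target_index: int) -> ScaleEstimate:
    """The default rule: pooled-LAD residuals, mean-deviation scale, floor 1."""
    return estimate_delta(pooled_lad_residuals(family, target_index))
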