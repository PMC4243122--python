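"""Edge scoring by stability selection over moving-block bootstrap families.

For each of N bootstrap replicates, every dataset is resampled at the level
of whole blocks of consecutive transitions (preserving short-range temporal
dependence), the grouped solver is run for every target gene along a shared
penalty grid, and an edge j -> i counts as selected whenever its coefficient
group is nonzero.  The per-penalty selection frequency is

    Pi_lam(i, j) = #{replicates selecting (i, j) at lam} / N

and the final score is Pi(i, j) = max over the grid of Pi_lam(i, j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .assembly import (
    DatasetFamily,
    TransitionSeries,
    as_transition_series,
    assemble_target,
)
from .robust_scale import delta_for_target
from .solver import SolverConfig, lambda_grid, lambda_max, solve_path

__all__ = [
    "BootstrapConfig",
    "EdgeFrequencyMatrix",
    "moving_block_bootstrap",
    "stability_select",
    "edges_at_threshold",
]

logger = logging.getLogger("hubernet")


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling and penalty-grid settings for stability selection."""

    n_bootstrap: int = 30
    block_length: int = 10
    seed: int = 0
    n_lambdas: int = 20
    lam_min_ratio: float = 0.01
    max_selected: int | None = None  # None: ceil(p / 2) per target

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        if self.n_lambdas < 2:
            raise ValueError("n_lambdas must be >= 2")
        if not 0.0 < self.lam_min_ratio < 1.0:
            raise ValueError("lam_min_ratio must be in (0, 1)")
        if self.max_selected is not None and self.max_selected < 1:
            raise ValueError("max_selected must be >= 1 (or None)")


@dataclass(frozen=True)
class EdgeFrequencyMatrix:
    """p x p stability scores in [0, 1].

    The diagonal is reported for completeness but self-regulation is excluded
    from topology scoring and from edge lists.
    """

    scores: np.ndarray
    gene_ids: tuple[str, ...]
    n_warnings: int = 0

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = scores.shape[0]
        if scores.shape != (p, p) or len(self.gene_ids) != p:
            raise ValueError("scores must be square and match gene_ids")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    @property
    def p(self) -> int:
        return self.scores.shape[0]


def moving_block_bootstrap(
    dataset, block_length: int, rng: np.random.Generator
) -> TransitionSeries:
    """Resample one dataset's transitions in overlapping consecutive blocks.

    The series of n transition pairs is split into n - l + 1 overlapping
    blocks of l consecutive pairs; floor(n / l) blocks are drawn with
    replacement and concatenated in drawn order.  Resampling whole
    transition pairs keeps every response aligned with its true predecessor,
    so no artificial transitions appear at block seams.
    """
    series = as_transition_series(dataset)
    n = series.n_transitions
    l = int(block_length)
    if l < 1:
        raise ValueError("block_length must be >= 1")
    if l > n:
        raise ValueError(f"block_length {l} exceeds the {n} available transitions")
    n_blocks = n // l
    starts = rng.integers(0, n - l + 1, size=n_blocks)
    idx = np.concatenate([np.arange(s, s + l) for s in starts])
    return TransitionSeries(
        series.predecessors[:, idx],
        series.successors[:, idx],
        series.gene_ids,
        series.dataset_id,
    )


def _bootstrap_family(
    family: DatasetFamily, block_length: int, seed_seq: np.random.SeedSequence
) -> DatasetFamily:
    children = seed_seq.spawn(family.m)
    resampled = [
        moving_block_bootstrap(series, block_length, np.random.default_rng(child))
        for series, child in zip(family.datasets, children)
    ]
    return DatasetFamily(resampled)


def estimate_deltas(family: DatasetFamily, solver: SolverConfig) -> np.ndarray:
    """Per-target Huber transition points from the original (un-resampled) data.

    Estimated once per target gene (pooled-LAD residual scale) and held
    fixed through the penalty grid and all bootstrap replicates, so
    robustness tuning is not conflated with resampling noise.  Ignored for
    the squared loss.
    """
    if solver.loss == "squared":
        return np.full(family.p, np.inf)
    deltas = np.empty(family.p)
    for i in range(family.p):
        est = delta_for_target(family, i)
        deltas[i] = est.delta
        logger.info("[solve] target %s: delta = %.4f (sigma_hat = %.4f)",
                    family.gene_ids[i], est.delta, est.sigma_hat)
    return deltas


def stability_select(
    family: DatasetFamily,
    config: BootstrapConfig,
    solver: SolverConfig | None = None,
    delta_override: float | None = None,
) -> EdgeFrequencyMatrix:
    """Score every edge by its maximal selection frequency over the grid.

    The penalty set Lambda is fixed up front from the original (un-resampled)
    family — a log grid from the largest per-target lambda_max down to
    ``lam_min_ratio`` times it — and every bootstrap replicate is solved at
    those same absolute penalties, so the frequency of an edge at a given
    lambda is comparable across replicates.
    ``delta_override`` bypasses the per-target MAD rule with a fixed value.

    Frequencies are accumulated only over the sparse stretch of the grid:
    once a target's solution holds more than ``max_selected`` nonzero groups
    (default: half the genes, rounded up), smaller penalties contribute
    nothing for that target in that replicate.  Without this restriction of
    the penalty region to sparse models — standard practice in stability
    selection — the small-penalty tail selects every group in every
    replicate and all scores saturate at 1.
    """
    if solver is None:
        solver = SolverConfig()
    p, N = family.p, config.n_bootstrap
    if delta_override is not None and solver.loss == "huber":
        deltas = np.full(p, float(delta_override))
    else:
        deltas = estimate_deltas(family, solver)
    # selection counts indexed (grid position, target gene i, regulator j)
    counts = np.zeros((config.n_lambdas, p, p))
    n_warnings = 0
    select_tol = 10.0 * solver.tol
    max_selected = (
        config.max_selected if config.max_selected is not None
        else -(-p // 2)
    )
    eff = [np.inf if solver.loss == "squared" else deltas[i] for i in range(p)]
    lam_max = max(
        lambda_max(assemble_target(family, i), eff[i]) for i in range(p)
    )
    grid = lambda_grid(lam_max, config.n_lambdas, config.lam_min_ratio)
    logger.info("[bootstrap] shared lambda_max = %.4f over %d penalties",
                lam_max, config.n_lambdas)
    replicate_seeds = np.random.SeedSequence(config.seed).spawn(N)
    for b, seed_seq in enumerate(replicate_seeds):
        boot = _bootstrap_family(family, config.block_length, seed_seq)
        problems = [assemble_target(boot, i) for i in range(p)]
        for i in range(p):
            cfg = solver if solver.loss == "squared" else SolverConfig(
                delta=deltas[i], tol=solver.tol,
                max_iter=solver.max_iter, loss="huber",
            )
            path = solve_path(problems[i], config=cfg, lambdas=grid)
            for g, result in enumerate(path.solutions):
                if not result.converged:
                    n_warnings += 1
                    continue  # treated as non-selecting
                support = result.coefficients.support(select_tol)
                if support.sum() > max_selected:
                    break  # left the sparse regularization region
                counts[g, i] += support
    if n_warnings:
        logger.warning("[bootstrap] %d non-converged solves treated as "
                       "non-selecting", n_warnings)
    scores = (counts / N).max(axis=0)
    return EdgeFrequencyMatrix(
        scores=scores, gene_ids=family.gene_ids, n_warnings=n_warnings
    )


def edges_at_threshold(
    scores: EdgeFrequencyMatrix, threshold: float
) -> list[tuple[str, str, float]]:
    """Off-diagonal edges scoring >= threshold as (regulator, target, score).

    Sorted by descending score, then row-major (target, regulator) order.
    Entry (i, j) of the score matrix is the edge from gene j to gene i.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    p = scores.p
    rows = []
    for i in range(p):
        for j in range(p):
            if i != j and scores.scores[i, j] >= threshold:
                rows.append(
                    (scores.gene_ids[j], scores.gene_ids[i],
                     float(scores.scores[i, j]), i, j)
                )
    rows.sort(key=lambda r: (-r[2], r[3], r[4]))
    return [(reg, tgt, score) for reg, tgt, score, _, _ in rows]
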