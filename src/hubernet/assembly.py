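"""Stacking multiple time-course datasets into per-target-gene regressions.

For target gene ``i`` the autoregressive model across ``m`` datasets is

    y_j ~ sum_l a_il(k) x_{l,t}(k)      (observation j = transition t of dataset k)

with one coefficient copy ``a_il(k)`` per dataset, grouped over ``k`` so that
the group LASSO can force the edge ``l -> i`` jointly in or out of every
dataset's matrix.  Observations are weighted by the per-dataset weights
``w_k`` (default proportional to dataset size).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ExpressionDataset, NetworkMatrix

__all__ = [
    "TransitionSeries",
    "DatasetFamily",
    "TargetRegression",
    "GroupCoefficients",
    "default_weights",
    "assemble_target",
]


@dataclass(frozen=True)
class TransitionSeries:
    """Paired predecessor/successor expression columns of one dataset.

    This is the resolution at which the regression — and the moving block
    bootstrap — operate: column ``t`` of ``predecessors`` maps to column
    ``t`` of ``successors`` under the dataset's regulatory matrix.
    """

    predecessors: np.ndarray
    successors: np.ndarray
    gene_ids: tuple[str, ...]
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        pre = np.asarray(self.predecessors, dtype=float)
        suc = np.asarray(self.successors, dtype=float)
        object.__setattr__(self, "predecessors", pre)
        object.__setattr__(self, "successors", suc)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if pre.shape != suc.shape or pre.ndim != 2:
            raise ValueError("predecessors and successors must be equal-shape 2-D")
        if pre.shape[1] < 1:
            raise ValueError("need at least one transition")
        if len(self.gene_ids) != pre.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset) -> "TransitionSeries":
        pre, suc = dataset.transitions()
        return cls(pre, suc, dataset.gene_ids, dataset.dataset_id)

    @property
    def p(self) -> int:
        return self.predecessors.shape[0]

    @property
    def n_transitions(self) -> int:
        return self.predecessors.shape[1]


def as_transition_series(dataset) -> TransitionSeries:
    if isinstance(dataset, TransitionSeries):
        return dataset
    if isinstance(dataset, ExpressionDataset):
        return TransitionSeries.from_dataset(dataset)
    raise TypeError(f"cannot interpret {type(dataset).__name__} as a time course")


class GeneOrderError(ValueError):
    """Datasets in a family do not share the same genes in the same order."""


@dataclass(frozen=True)
class DatasetFamily:
    """An ordered collection of aligned datasets with per-dataset weights.

    ``standardize=True`` rescales each gene's row to unit standard deviation
    within each dataset (no centering — the model has no intercept).
    """

    datasets: tuple[TransitionSeries, ...]
    weights: np.ndarray = None
    standardize: bool = False

    def __init__(self, datasets, weights=None, standardize: bool = False):
        series = tuple(as_transition_series(d) for d in datasets)
        if not series:
            raise ValueError("family must contain at least one dataset")
        gene_ids = series[0].gene_ids
        for s in series[1:]:
            if s.gene_ids != gene_ids:
                raise GeneOrderError(
                    f"dataset {s.dataset_id!r} gene order differs from "
                    f"{series[0].dataset_id!r}"
                )
        if standardize:
            series = tuple(_standardize(s) for s in series)
        object.__setattr__(self, "datasets", series)
        object.__setattr__(self, "standardize", standardize)
        if weights is None:
            weights = default_weights(self)
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (len(series),):
            raise ValueError("need one weight per dataset")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", weights)

    @property
    def m(self) -> int:
        return len(self.datasets)

    @property
    def p(self) -> int:
        return self.datasets[0].p

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.datasets[0].gene_ids

    @property
    def n_per_dataset(self) -> np.ndarray:
        return np.array([d.n_transitions for d in self.datasets])


def _standardize(series: TransitionSeries) -> TransitionSeries:
    full = np.concatenate([series.predecessors, series.successors[:, -1:]], axis=1)
    scale = full.std(axis=1, ddof=0)
    scale[scale == 0] = 1.0
    return TransitionSeries(
        series.predecessors / scale[:, None],
        series.successors / scale[:, None],
        series.gene_ids,
        series.dataset_id,
    )


def default_weights(family: DatasetFamily) -> np.ndarray:
    """Size-proportional dataset weights ``w_k = n_k / sum(n_k)``."""
    n = np.array([d.n_transitions for d in family.datasets], dtype=float)
    if n.sum() <= 0:
        raise ValueError("family has no transitions")
    return n / n.sum()


@dataclass(frozen=True)
class TargetRegression:
    """The stacked regression problem for one target gene.

    ``design`` is the dense ``n x (p*m)`` block design: the coefficient for
    regulator ``l`` in dataset ``k`` sits at column ``l*m + k``, and the row
    for an observation from dataset ``k`` is nonzero only in that dataset's
    columns (block-diagonal across datasets).
    """

    target_index: int
    y: np.ndarray
    design: np.ndarray
    obs_weights: np.ndarray
    n_groups: int
    group_size: int
    dataset_slices: tuple[slice, ...]
    gene_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def design_block(self, k: int) -> np.ndarray:
        """Dataset k's p x n_k predictor matrix (first n_k timepoints)."""
        rows = self.dataset_slices[k]
        return self.design[rows, k :: self.group_size].T.copy()

    @property
    def design_blocks(self) -> list[np.ndarray]:
        return [self.design_block(k) for k in range(self.group_size)]

    def group_slice(self, group: int) -> slice:
        return slice(group * self.group_size, (group + 1) * self.group_size)


@dataclass(frozen=True)
class GroupCoefficients:
    """Coefficients for one target gene: p groups of m per-dataset copies."""

    groups: np.ndarray  # shape (p, m): groups[l, k] = a_il(k)

    def __post_init__(self) -> None:
        groups = np.asarray(self.groups, dtype=float)
        if groups.ndim != 2:
            raise ValueError("groups must be a p x m array")
        object.__setattr__(self, "groups", groups)

    @classmethod
    def from_flat(cls, flat: np.ndarray, n_groups: int, group_size: int):
        return cls(np.asarray(flat, dtype=float).reshape(n_groups, group_size))

    @classmethod
    def from_networks(cls, networks: list[NetworkMatrix], target_index: int):
        """True coefficients for gene i read off the generating matrices."""
        return cls(np.column_stack([A.values[target_index] for A in networks]))

    @property
    def flat(self) -> np.ndarray:
        return self.groups.reshape(-1)

    @property
    def n_groups(self) -> int:
        return self.groups.shape[0]

    @property
    def group_size(self) -> int:
        return self.groups.shape[1]

    def group_norms(self) -> np.ndarray:
        return np.linalg.norm(self.groups, axis=1)

    def support(self, tol: float = 0.0) -> np.ndarray:
        return self.group_norms() > tol


def assemble_target(family: DatasetFamily, target_index: int) -> TargetRegression:
    """Stack all datasets into the grouped regression for one target gene."""
    p, m = family.p, family.m
    if not 0 <= target_index < p:
        raise IndexError(f"target_index {target_index} out of range for p={p}")
    n_k = family.n_per_dataset
    n = int(n_k.sum())
    y = np.empty(n)
    X = np.zeros((n, p * m))
    w = np.empty(n)
    slices = []
    offset = 0
    for k, series in enumerate(family.datasets):
        rows = slice(offset, offset + series.n_transitions)
        slices.append(rows)
        y[rows] = series.successors[target_index]
        # columns l*m + k for l = 0..p-1, i.e. a stride-m slice starting at k
        X[rows, k::m] = series.predecessors.T
        w[rows] = family.weights[k]
        offset += series.n_transitions
    return TargetRegression(
        target_index=target_index,
        y=y,
        design=X,
        obs_weights=w,
        n_groups=p,
        group_size=m,
        dataset_slices=tuple(slices),
        gene_ids=family.gene_ids,
    )
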