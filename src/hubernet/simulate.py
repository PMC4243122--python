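"""Synthetic time-course expression data from a known regulatory topology.

The generator emulates the discrete-time linear dynamics of a small gene
regulatory network: expression at time ``t+1`` is a linear map ``A`` of
expression at time ``t`` plus measurement error, where the zero pattern of
``A`` encodes the network topology (entry ``(i, j) != 0`` means gene ``j``
regulates gene ``i``).  Several "condition" matrices ``A(k)`` share one sign
pattern but differ in regulatory strength, and each produces its own
time-course dataset.  Measurement error is a two-component Gaussian scale
mixture so that a fixed fraction of observations are gross outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkMatrix",
    "SimulationConfig",
    "ExpressionDataset",
    "paper_template",
    "generate_network_family",
    "simulate_timecourse",
    "simulate_family",
    "generate_family",
    "draw_mixture_noise",
]


class SimulationError(RuntimeError):
    """Raised when a stable network matrix cannot be produced."""


@dataclass(frozen=True)
class NetworkMatrix:
    """A signed, weighted regulatory matrix for ``x_t = A x_{t-1}``.

    ``values[i, j]`` is the strength with which gene ``j`` drives gene ``i``;
    ``signs`` holds the topology template in ``{-1, 0, +1}``.
    """

    values: np.ndarray
    signs: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        signs = np.asarray(self.signs, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        p = values.shape[0]
        if values.ndim != 2 or values.shape != (p, p) or p < 2:
            raise ValueError("network matrix must be square with p >= 2")
        if signs.shape != values.shape:
            raise ValueError("signs and values must have the same shape")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must match matrix size")
        if not np.all(np.isin(signs, (-1, 0, 1))):
            raise ValueError("signs must be in {-1, 0, +1}")
        if np.any(np.sign(values).astype(int)[signs != 0] != signs[signs != 0]):
            raise ValueError("values disagree with the sign template")
        if np.any(values[signs == 0] != 0.0):
            raise ValueError("values must be zero where the template is zero")

    @property
    def p(self) -> int:
        return self.values.shape[0]

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.values))))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family of datasets.

    ``n_obs`` is the number of transitions per dataset, so each dataset has
    ``n_obs + 1`` timepoints.  The error mixture draws ``N(0, sd_small^2)``
    with probability ``1 - contamination_prob`` and ``N(0, sd_large^2)``
    otherwise.
    """

    m: int = 4
    n_obs: int = 15
    contamination_prob: float = 0.2
    sd_small: float = 1.0
    sd_large: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_obs < 2:
            raise ValueError("n_obs must be >= 2")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise ValueError("contamination_prob must be in [0, 1]")
        if self.sd_small <= 0 or self.sd_large <= 0:
            raise ValueError("noise standard deviations must be positive")


@dataclass(frozen=True)
class ExpressionDataset:
    """One gene x timepoint expression matrix for a single experiment."""

    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x timepoints)")
        if matrix.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if len(self.gene_ids) != matrix.shape[0]:
            raise ValueError("gene_ids length must match the number of rows")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("expression values must be finite")

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_transitions(self) -> int:
        return self.matrix.shape[1] - 1

    def transitions(self) -> tuple[np.ndarray, np.ndarray]:
        """Predecessor and successor columns of consecutive timepoint pairs."""
        return self.matrix[:, :-1], self.matrix[:, 1:]


# The fixed 5-gene benchmark topology: row i lists the regulators of gene i.
_TEMPLATE_SIGNS = np.array(
    [
        [+1, -1, +1, 0, 0],
        [-1, +1, 0, 0, +1],
        [0, +1, +1, 0, 0],
        [+1, -1, 0, +1, 0],
        [0, 0, 0, +1, +1],
    ],
    dtype=int,
)


def paper_template() -> NetworkMatrix:
    """The 5-gene signed benchmark template ``A0``."""
    signs = _TEMPLATE_SIGNS.copy()
    return NetworkMatrix(
        values=signs.astype(float),
        signs=signs,
        gene_ids=tuple(f"G{i + 1}" for i in range(signs.shape[0])),
    )


def generate_network_family(
    template: NetworkMatrix,
    m: int,
    rng: np.random.Generator,
    magnitude_range: tuple[float, float] = (0.2, 1.0),
    radius_range: tuple[float, float] = (0.7, 0.95),
) -> list[NetworkMatrix]:
    """Draw ``m`` stable matrices sharing the template's exact sign pattern.

    Nonzero magnitudes are uniform on ``magnitude_range`` with the template's
    sign; the matrix is then rescaled so its spectral radius equals a target
    drawn uniformly on ``radius_range``, which guarantees stability of the
    discrete dynamics without rejection sampling while keeping entries
    bounded away from zero.  The radius range keeps the dynamics persistent:
    innovations propagate through several transitions, so the lagged
    expression carries regulatory signal well above the small-noise floor
    across the whole observation window.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    signs = template.signs
    out: list[NetworkMatrix] = []
    for _ in range(m):
        mags = rng.uniform(*magnitude_range, size=signs.shape)
        values = signs * mags
        rho = float(np.max(np.abs(np.linalg.eigvals(values))))
        if rho <= 0.0:
            raise SimulationError(
                "template admits no stable rescaling (zero spectral radius)"
            )
        target = rng.uniform(*radius_range)
        values *= target / rho
        out.append(NetworkMatrix(values=values, signs=signs.copy(),
                                 gene_ids=template.gene_ids))
    return out


def draw_mixture_noise(
    rng: np.random.Generator,
    size,
    contamination_prob: float,
    sd_small: float,
    sd_large: float,
) -> np.ndarray:
    """Two-component Gaussian scale-mixture errors."""
    u = rng.random(size)
    z = rng.standard_normal(size)
    sd = np.where(u < contamination_prob, sd_large, sd_small)
    return sd * z


def simulate_timecourse(
    A: NetworkMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
    dataset_id: str = "dataset",
) -> ExpressionDataset:
    """One noisy trajectory ``x_{t+1} = A x_t + e_t`` of ``n_obs + 1`` timepoints.

    The first timepoint is i.i.d. uniform on [1, 10]; noise enters the
    recursion directly, so it accumulates through the trajectory exactly as
    the autoregressive measurement model prescribes.
    """
    p = A.p
    X = np.empty((p, config.n_obs + 1))
    X[:, 0] = rng.uniform(1.0, 10.0, size=p)
    for t in range(config.n_obs):
        e = draw_mixture_noise(
            rng, p, config.contamination_prob, config.sd_small, config.sd_large
        )
        X[:, t + 1] = A.values @ X[:, t] + e
    return ExpressionDataset(matrix=X, gene_ids=A.gene_ids, dataset_id=dataset_id)


def simulate_family(
    template: NetworkMatrix, config: SimulationConfig
) -> tuple[list[ExpressionDataset], list[NetworkMatrix]]:
    """Generate ``m`` datasets, each from its own sign-consistent stable A(k).

    One master seed; per-dataset substreams are spawned deterministically so
    that increasing ``m`` leaves earlier datasets unchanged.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.m)
    datasets: list[ExpressionDataset] = []
    networks: list[NetworkMatrix] = []
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        (A,) = generate_network_family(template, 1, rng)
        datasets.append(
            simulate_timecourse(A, config, rng, dataset_id=f"dataset{k + 1}")
        )
        networks.append(A)
    return datasets, networks


def generate_family(
    template: NetworkMatrix, config: SimulationConfig
) -> list[ExpressionDataset]:
    """Datasets only; see :func:`simulate_family` for the true matrices too."""
    return simulate_family(template, config)[0]
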