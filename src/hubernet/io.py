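"""Plain-text formats: expression tables, score matrices, edge lists, configs.

The canonical expression format is a TSV with a header row: first column
gene identifiers, remaining columns timepoints in temporal order.  CSV is
accepted by delimiter sniffing.  Edge lists use the 3-column
(regulator, target, weight) convention of common network benchmarks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionDataset, NetworkMatrix
from .stability import EdgeFrequencyMatrix, edges_at_threshold
from .evaluation import GoldStandard

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_edge_scores",
    "read_score_matrix",
    "write_score_matrix",
    "write_network_matrix",
    "read_gold_standard",
    "write_edge_list",
]


class TableFormatError(ValueError):
    """A text table failed validation; the message names the offending cell."""


def _sniff_delimiter(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if header.count(",") > header.count("\t") else "\t"


def _read_table(path) -> pd.DataFrame:
    # C engine with round-trip floats so write -> read is bit-exact
    return pd.read_csv(path, sep=_sniff_delimiter(path), index_col=0,
                       float_precision="round_trip")


def read_expression_tsv(path) -> ExpressionDataset:
    """Read a genes x timepoints table (TSV or CSV, sniffed)."""
    path = Path(path)
    df = _read_table(path)
    if df.shape[1] < 2:
        raise TableFormatError(
            f"{path.name}: need at least 2 timepoint columns, found {df.shape[1]}"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise TableFormatError(
            f"{path.name}: non-numeric or missing value at gene "
            f"{df.index[i]!r}, column {df.columns[j]!r}"
        )
    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=float),
        gene_ids=tuple(str(g) for g in df.index),
        dataset_id=path.stem,
    )


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    df = pd.DataFrame(
        dataset.matrix,
        index=list(dataset.gene_ids),
        columns=[f"t{t}" for t in range(dataset.matrix.shape[1])],
    )
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_score_matrix(scores: EdgeFrequencyMatrix, path) -> None:
    df = pd.DataFrame(scores.scores, index=list(scores.gene_ids),
                      columns=list(scores.gene_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_score_matrix(path) -> EdgeFrequencyMatrix:
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise TableFormatError(f"{Path(path).name}: score matrix must be square")
    return EdgeFrequencyMatrix(
        scores=df.to_numpy(dtype=float),
        gene_ids=tuple(str(g) for g in df.index),
    )


def write_edge_scores(
    scores: EdgeFrequencyMatrix, path, matrix_path=None
) -> None:
    """Tab-separated (regulator, target, score), descending score, no self-pairs."""
    rows = edges_at_threshold(scores, 0.0)
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tscore\n")
        for reg, tgt, score in rows:
            fh.write(f"{reg}\t{tgt}\t{score!r}\n")
    if matrix_path is not None:
        write_score_matrix(scores, matrix_path)


def write_network_matrix(network: NetworkMatrix, path) -> None:
    df = pd.DataFrame(network.values, index=list(network.gene_ids),
                      columns=list(network.gene_ids))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_edge_list(network: NetworkMatrix, path) -> None:
    """Template topology as (regulator, target, sign) rows; no self-loops."""
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\tsign\n")
        for i in range(network.p):
            for j in range(network.p):
                if i != j and network.signs[i, j] != 0:
                    fh.write(
                        f"{network.gene_ids[j]}\t{network.gene_ids[i]}\t"
                        f"{network.signs[i, j]:+d}\n"
                    )


def read_gold_standard(path, gene_ids: tuple[str, ...] | None = None) -> GoldStandard:
    """Read a gold standard as a signed matrix TSV or a 3-column edge list."""
    path = Path(path)
    probe = pd.read_csv(path, sep=_sniff_delimiter(path))
    first = str(probe.columns[0]).lower()
    if first in ("regulator", "source", "from"):
        if gene_ids is None:
            names = sorted(set(probe.iloc[:, 0]) | set(probe.iloc[:, 1]))
            gene_ids = tuple(str(g) for g in names)
        index = {g: i for i, g in enumerate(gene_ids)}
        adj = np.zeros((len(gene_ids), len(gene_ids)), dtype=int)
        for _, row in probe.iterrows():
            reg, tgt = str(row.iloc[0]), str(row.iloc[1])
            if reg not in index or tgt not in index:
                raise TableFormatError(
                    f"{path.name}: edge {reg}->{tgt} names an unknown gene"
                )
            sign = int(np.sign(float(row.iloc[2]))) if probe.shape[1] > 2 else 1
            adj[index[tgt], index[reg]] = sign if sign != 0 else 1
        return GoldStandard(adjacency=adj, gene_ids=gene_ids)
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise TableFormatError(f"{path.name}: gold matrix must be square")
    return GoldStandard(
        adjacency=np.sign(df.to_numpy(dtype=float)).astype(int),
        gene_ids=tuple(str(g) for g in df.index),
    )


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of one end-to-end run; JSON round-trippable."""

    # simulation (ignored when expression_paths is set)
    m: int = 4
    n_obs: int = 15
    contamination_prob: float = 0.2
    sd_small: float = 1.0
    sd_large: float = 10.0
    # inference
    losses: tuple[str, ...] = ("huber", "squared")
    n_bootstrap: int = 30
    block_length: int = 10
    n_lambdas: int = 20
    lam_min_ratio: float = 0.01
    delta: float | None = None  # override of the per-target MAD rule
    tol: float = 1e-6
    max_iter: int = 10_000
    standardize: bool = False
    # plumbing
    seed: int = 0
    expression_paths: tuple[str, ...] = ()
    gold_path: str | None = None
    outdir: str | None = None
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["losses"] = tuple(raw.get("losses", ()))
        raw["expression_paths"] = tuple(raw.get("expression_paths", ()))
        return cls(**raw)
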