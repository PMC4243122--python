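"""End-to-end composition: simulate (or load) -> infer -> evaluate.

Also hosts the benchmark driver that replays the 5-gene simulation protocol
over replicate seeds, which the acceptance machinery and the `run-paper-sim`
command share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .assembly import DatasetFamily
from .evaluation import GoldStandard, roc_pr_curves
from .simulate import SimulationConfig, paper_template, simulate_family
from .solver import SolverConfig
from .stability import BootstrapConfig, stability_select

__all__ = ["Situation", "TABLE_SITUATIONS", "end_to_end",
           "run_simulation_benchmark", "benchmark_medians"]

logger = logging.getLogger("hubernet")


@dataclass(frozen=True)
class Situation:
    """One simulation study condition: dataset count, length, block length."""

    m: int
    n_obs: int
    block_length: int

    @property
    def label(self) -> str:
        return f"m{self.m}_n{self.n_obs}"


# The three benchmark conditions; 30 bootstrap replicates each, block
# length 10 for the 15-observation settings and 5 for the 8-observation one.
TABLE_SITUATIONS = (
    Situation(m=8, n_obs=15, block_length=10),
    Situation(m=4, n_obs=15, block_length=10),
    Situation(m=4, n_obs=8, block_length=5),
)


def _derived_seeds(master_seed: int, n: int, tag: int) -> list[int]:
    """Deterministic child seeds (< 2**31) for replicate r of stream `tag`."""
    return [
        int(np.random.SeedSequence([master_seed, tag, r]).generate_state(1)[0]
            % (2**31))
        for r in range(n)
    ]


def run_one(
    situation: Situation,
    loss: str,
    seed: int,
    contamination_prob: float = 0.2,
    n_bootstrap: int = 30,
    n_lambdas: int = 20,
    lam_min_ratio: float = 0.01,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """Simulate one family under a condition, infer, and score: (AUROC, AUPR)."""
    template = paper_template()
    sim_seed, boot_seed = _derived_seeds(seed, 2, tag=7)
    sim = SimulationConfig(
        m=situation.m, n_obs=situation.n_obs,
        contamination_prob=contamination_prob, seed=sim_seed,
    )
    datasets, _ = simulate_family(template, sim)
    family = DatasetFamily(datasets)
    scores = stability_select(
        family,
        BootstrapConfig(
            n_bootstrap=n_bootstrap, block_length=situation.block_length,
            seed=boot_seed, n_lambdas=n_lambdas, lam_min_ratio=lam_min_ratio,
        ),
        SolverConfig(loss=loss, tol=tol),
    )
    curves = roc_pr_curves(scores, GoldStandard.from_network(template))
    return curves.auroc, curves.aupr


def run_simulation_benchmark(
    situations=TABLE_SITUATIONS,
    losses=("huber", "squared"),
    n_replicates: int = 10,
    master_seed: int = 0,
    contamination_prob: float = 0.2,
    n_bootstrap: int = 30,
) -> pd.DataFrame:
    """The full simulation protocol over replicate seeds.

    Returns one row per (situation, loss, replicate) with AUROC and AUPR of
    the stability-selection scores against the template topology.
    """
    seeds = _derived_seeds(master_seed, n_replicates, tag=11)
    rows = []
    for situation in situations:
        for loss in losses:
            for r, seed in enumerate(seeds):
                auroc, aupr = run_one(
                    situation, loss, seed,
                    contamination_prob=contamination_prob,
                    n_bootstrap=n_bootstrap,
                )
                logger.info(
                    "[evaluate] %s %s replicate %d: AUROC=%.4f AUPR=%.4f",
                    situation.label, loss, r, auroc, aupr,
                )
                rows.append({
                    "situation": situation.label, "m": situation.m,
                    "n_obs": situation.n_obs, "loss": loss,
                    "replicate": r, "seed": seed,
                    "auroc": auroc, "aupr": aupr,
                })
    return pd.DataFrame(rows)


def benchmark_medians(results: pd.DataFrame) -> pd.DataFrame:
    """Median AUROC/AUPR per (situation, loss) over replicates."""
    return (
        results.groupby(["situation", "loss"])[["auroc", "aupr"]]
        .median()
        .reset_index()
    )


def end_to_end(run: hio.RunConfig) -> dict:
    """Simulate or load data, run stability selection per loss, evaluate.

    Writes (when ``run.outdir`` is set) the resolved config, per-loss edge
    lists and score matrices, and a machine-readable summary; returns the
    summary dict either way.
    """
    logging.basicConfig(level=run.log_level)
    outdir = Path(run.outdir) if run.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        run.to_json(outdir / "config.json")
    template = paper_template()
    if run.expression_paths:
        logger.info("[simulate] loading %d user datasets", len(run.expression_paths))
        datasets = [hio.read_expression_tsv(p) for p in run.expression_paths]
        gold = (hio.read_gold_standard(run.gold_path, datasets[0].gene_ids)
                if run.gold_path else None)
    else:
        logger.info("[simulate] generating %d datasets of %d transitions",
                    run.m, run.n_obs)
        sim = SimulationConfig(
            m=run.m, n_obs=run.n_obs, contamination_prob=run.contamination_prob,
            sd_small=run.sd_small, sd_large=run.sd_large, seed=run.seed,
        )
        datasets, networks = simulate_family(template, sim)
        gold = GoldStandard.from_network(template)
        if outdir:
            for k, (ds, net) in enumerate(zip(datasets, networks)):
                hio.write_expression_tsv(ds, outdir / f"expression_{k + 1}.tsv")
                hio.write_network_matrix(net, outdir / f"true_A_{k + 1}.tsv")
            hio.write_edge_list(template, outdir / "template_edges.tsv")
    family = DatasetFamily(datasets, standardize=run.standardize)
    boot = BootstrapConfig(
        n_bootstrap=run.n_bootstrap, block_length=run.block_length,
        seed=run.seed + 1, n_lambdas=run.n_lambdas,
        lam_min_ratio=run.lam_min_ratio,
    )
    summary: dict = {"losses": {}, "p": family.p, "m": family.m}
    for loss in run.losses:
        logger.info("[bootstrap] stability selection with %s loss", loss)
        solver = SolverConfig(loss=loss, tol=run.tol, max_iter=run.max_iter)
        scores = stability_select(family, boot, solver,
                                  delta_override=run.delta)
        entry: dict = {"n_warnings": scores.n_warnings}
        if outdir:
            hio.write_edge_scores(
                scores,
                outdir / f"edges_{loss}.tsv",
                matrix_path=outdir / f"scores_{loss}.tsv",
            )
        if gold is not None:
            curves = roc_pr_curves(scores, gold)
            entry["auroc"] = curves.auroc
            entry["aupr"] = curves.aupr
            logger.info("[evaluate] %s: AUROC=%.4f AUPR=%.4f",
                        loss, curves.auroc, curves.aupr)
        summary["losses"][loss] = entry
    if outdir:
        import json

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return summary
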