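import numpy as np
import pytest

from hubernet import (
    DatasetFamily,
    ExpressionDataset,
    GoldStandard,
    SimulationConfig,
    assemble_target,
    paper_template,
    simulate_family,
)


@pytest.fixture(scope="session")
def template():
    return paper_template()


@pytest.fixture(scope="session")
def gold(template):
    return GoldStandard.from_network(template)


def make_random_family(m=2, p=4, n_obs=10, seed=0, scale=1.0):
    """Aligned random expression datasets (no network structure)."""
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"g{i}" for i in range(p))
    datasets = [
        ExpressionDataset(
            scale * rng.normal(size=(p, n_obs + 1)), gene_ids, f"d{k}"
        )
        for k in range(m)
    ]
    return DatasetFamily(datasets)


def make_random_problem(m=2, p=4, n_obs=10, seed=0, target=0, scale=1.0):
    """A random stacked target regression for solver-level tests."""
    return assemble_target(make_random_family(m, p, n_obs, seed, scale), target)


def make_simulated_family(m=4, n_obs=15, seed=0, contamination=0.2):
    """A family drawn from the 5-gene benchmark template."""
    datasets, networks = simulate_family(
        paper_template(),
        SimulationConfig(m=m, n_obs=n_obs, contamination_prob=contamination,
                         seed=seed),
    )
    return DatasetFamily(datasets), networks


@pytest.fixture
def simulated_family():
    return make_simulated_family()
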