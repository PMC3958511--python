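import numpy as np
import pytest

from corisk.io_formats import ExpressionDataset, GODag
from corisk.synthetic import PlantedModule, SimulationConfig, simulate


@pytest.fixture
def sibling_dag() -> GODag:
    """Root R with two is_a children A and B."""
    return GODag.from_edges([("A", "R", "is_a"), ("B", "R", "is_a")])


@pytest.fixture
def chain_dag() -> GODag:
    """R <-(is_a)- X <-(part_of)- A."""
    return GODag.from_edges([("X", "R", "is_a"), ("A", "X", "part_of")])


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study for fast integration-style tests."""
    cfg = SimulationConfig(
        n_genes=60, n_tumor=12, n_normal=12,
        modules=[PlantedModule(5, 0.9, 2.5), PlantedModule(5, 0.9, 2.5),
                 PlantedModule(5, 0.9, 0.0), PlantedModule(5, 0.9, 0.0)],
        n_decoy_subtrees=4, n_decoy_complexes=4, seed=11)
    return simulate(cfg)


def make_dataset(values: np.ndarray, n_tumor: int, n_normal: int,
                 genes=None) -> ExpressionDataset:
    """Dataset with tumor columns first, then normal."""
    values = np.asarray(values, dtype=float)
    n_genes = values.shape[0]
    return ExpressionDataset(
        genes=genes or [f"G{i + 1}" for i in range(n_genes)],
        samples=[f"S{i + 1}" for i in range(n_tumor + n_normal)],
        labels=["tumor"] * n_tumor + ["normal"] * n_normal,
        values=values)


def dataset_with_significant_tumor_count(n_sig: int, n_tumor: int = 28,
                                         n_normal: int = 10, seed: int = 0):
    """3-gene module dataset where exactly *n_sig* of the tumor samples are
    Z-test significant against the normal-sample reference."""
    rng = np.random.default_rng(seed)
    values = np.empty((3, n_tumor + n_normal))
    normal_block = rng.standard_normal((3, n_normal))
    values[:, n_tumor:] = normal_block
    ref_means = normal_block.mean(axis=0)
    x_bar, sigma = ref_means.mean(), ref_means.std(ddof=0)
    # significant tumor samples sit 10 sigma out; the rest exactly at x_bar
    values[:, :n_sig] = x_bar + 10 * sigma
    values[:, n_sig:n_tumor] = x_bar
    return make_dataset(values, n_tumor=n_tumor, n_normal=n_normal)
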