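import numpy as np
import pytest

from cipher.data_io import ExpressionDataset
from cipher.simulate import make_perturbation_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Six cells x four genes, two perturbations, hand-checkable numbers."""
    counts = np.array([
        [5, 0, 3, 1],   # control
        [4, 1, 2, 0],   # control
        [6, 0, 4, 2],   # control
        [9, 0, 3, 1],   # GENE_A perturbed
        [8, 1, 2, 0],   # GENE_A perturbed
        [2, 3, 9, 1],   # GENE_C perturbed
    ], dtype=float)
    return ExpressionDataset(
        counts=counts,
        gene_ids=np.array(["GENE_A", "GENE_B", "GENE_C", "GENE_D"], dtype=object),
        cell_ids=np.array([f"c{i}" for i in range(6)], dtype=object),
        perturbation=np.array(["control", "control", "control",
                               "GENE_A", "GENE_A", "GENE_C"], dtype=object),
        control_label="control",
    )


@pytest.fixture(scope="session")
def planted_fixture():
    """Small screen-like count dataset with planted covariance (session-cached)."""
    ds, truth = make_perturbation_fixture(
        n_genes=40, n_control_cells=300, n_cells_per_perturbation=120,
        n_perturbations=3, seed=11)
    return ds, truth
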