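import numpy as np
import pandas as pd
import pytest

from crossdiff.data import ExpressionMatrix
from crossdiff.simdata import SimConfig, generate_dataset


def make_matrix(values, strains, treatments, collectives=None, genes=None):
    """Assemble an ExpressionMatrix from a plain array and label lists."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = pd.DataFrame(
        {"strain": strains, "treatment": treatments},
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        samples,
        collectives,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A compact 4-strain dataset with planted classes (fast, shared)."""
    cfg = SimConfig(
        n_genes=600,
        class_counts={
            "TYPE_I_UP": 10, "TYPE_I_DOWN": 5,
            "TYPE_II_SENS_UP": 8, "TYPE_II_SENS_DOWN": 8,
            "TYPE_II_RES_UP": 3, "TYPE_II_RES_DOWN": 3,
            "SINGLE_STRAIN": 40,
        },
        seed=42,
    )
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def default_sim():
    """The full-scale default design (8605 genes), generated once."""
    cfg = SimConfig(seed=7)
    matrix, truth = generate_dataset(cfg)
    return cfg, matrix, truth
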