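import numpy as np
import pandas as pd
import pytest

from lncluster.data_io import ExpressionMatrix
from lncluster.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 3-cluster cohort (60 tumors, 10 normals) shared across tests."""
    return simulate_cohort(SimulationConfig.tiny(seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Default 5-cluster preset cohort (200 tumors, 20 normals)."""
    return simulate_cohort(SimulationConfig(seed=11))


def make_expression(values, gene_ids=None, sample_ids=None,
                    gene_class="lncRNA", sample_role="tumor"):
    """Build a valid ExpressionMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"S{j}" for j in range(n_samples)]
    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    if isinstance(gene_class, str):
        gene_class = [gene_class] * n_genes
    if isinstance(sample_role, str):
        sample_role = [sample_role] * n_samples
    return ExpressionMatrix(frame, pd.Series(gene_class, index=frame.index),
                            pd.Series(sample_role, index=frame.columns))
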