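import numpy as np
import pandas as pd
import pytest

import tissueclock as tc


@pytest.fixture
def tiny_matrix():
    """3 genes x 2 samples, raw scale — the quantile-normalization worked case."""
    return tc.ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2"],
        values=np.array([[2.0, 1.0], [5.0, 4.0], [3.0, 4.0]]),
        scale="raw",
    )


@pytest.fixture
def two_tissue_table():
    return tc.SampleTable(pd.DataFrame({
        "sample_id": ["a1", "a2", "a3", "b1", "b2"],
        "donor_id": ["d1", "d2", "d3", "d1", "d2"],
        "tissue": ["A", "A", "A", "B", "B"],
        "age": [30, 40, 50, 30, 40],
        "sex": ["male", "female", "male", "male", "female"],
    }))


@pytest.fixture(scope="session")
def small_cohort():
    """Fast two-tissue cohort with full donor overlap and clear age signal."""
    config = tc.SimulationConfig(
        n_donors=60, tissues=(("A", 1.0), ("B", 1.0)), n_genes=200,
        n_shared_age_genes=15, noise_sd=0.3, tissue_age_noise_sd=2.0, seed=42,
    )
    return tc.simulate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study condition: 300 donors, two tissues at 80%
    inclusion, 2,000 genes with 50 shared causal genes."""
    return tc.simulate_cohort(tc.SimulationConfig(seed=1))


def prepare(matrix):
    """Raw matrix -> quantile-normalized log2 matrix (the modelling scale)."""
    return tc.log2_transform(tc.quantile_normalize(matrix))


@pytest.fixture(scope="session")
def default_dataset_a(default_cohort):
    """Tissue-A single-tissue CV dataset of the reference cohort."""
    matrix = prepare(default_cohort.matrices["tissueA"])
    table = default_cohort.table.for_tissue("tissueA")
    return tc.make_single_dataset(matrix, table)
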