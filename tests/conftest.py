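import numpy as np
import pandas as pd
import pytest

from cabsig import CohortDesign, ExpressionMatrix, GeneSignature, generate_cohort


def make_matrix(values, gene_ids=None, sample_ids=None, metadata=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), metadata
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_matrix():
    return make_matrix(
        [[1.0, 2.0, 3.0, 4.0, 5.0],
         [5.0, 4.0, 3.0, 2.0, 1.0],
         [2.0, 2.0, 2.0, 2.0, 9.0],
         [7.0, 8.0, 9.0, 6.0, 5.0],
         [0.0, 1.0, 0.0, 1.0, 0.0]]
    )


@pytest.fixture(scope="session")
def two_group_cohort():
    """Well-separated activated/quiescent cohort at the reference design."""
    design = CohortDesign.two_group(seed=7)
    matrix, meta = generate_cohort(design)
    signature = GeneSignature.from_ids(
        [f"SIG{j + 1:03d}" for j in range(design.m_signature)], name="sig"
    )
    return design, matrix, meta, signature
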