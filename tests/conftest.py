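import numpy as np
import pytest
import scipy.sparse as sp

from mprog.datamodel import CountMatrix
from mprog.synthetic import default_spec, generate_mouse_cohorts


def make_count_matrix(
    counts: np.ndarray,
    gene_ids=None,
    cell_ids=None,
    cohort=None,
    sample_id=None,
    malignant=None,
) -> CountMatrix:
    """Hand-built CountMatrix with sensible defaults for tests."""
    counts = np.asarray(counts)
    g, n = counts.shape
    return CountMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        cohort=np.array(cohort if cohort is not None else ["A"] * n, dtype=object),
        sample_id=np.array(
            sample_id if sample_id is not None else ["s1"] * n, dtype=object
        ),
        malignant=np.array(
            malignant if malignant is not None else [True] * n, dtype=bool
        ),
    )


@pytest.fixture(scope="session")
def small_spec():
    """Scaled-down study conditions for fast end-to-end tests."""
    return default_spec(seed=7, n_genes=400, n_cells_per_cohort=150)


@pytest.fixture(scope="session")
def small_mouse(small_spec):
    return generate_mouse_cohorts(small_spec)
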