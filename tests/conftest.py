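import numpy as np
import pytest
import scipy.sparse as sp

import dermalscore as ds


@pytest.fixture(scope="session")
def small_cohort():
    """One modest default-design cohort shared across read-only tests."""
    spec = ds.default_cohort_spec(cells_per_donor=300, n_genes=1200, seed=11)
    cm, meta, gt = ds.generate_cohort(spec)
    return cm, meta, gt


@pytest.fixture(scope="session")
def filtered_normalized(small_cohort):
    cm, meta, gt = small_cohort
    kept, report = ds.qc_filter(cm, meta=meta)
    meta = meta.set_index("cell_id").loc[kept.cell_ids].reset_index()
    return kept, ds.normalize(kept), meta


def toy_matrix(counts, symbols=None, cell_prefix="c"):
    """Build a CountMatrix from a dense array of counts."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    symbols = symbols or [f"G{j}" for j in range(n_genes)]
    return ds.CountMatrix(
        cell_ids=np.array([f"{cell_prefix}{i}" for i in range(n_cells)], dtype=object),
        gene_ids=np.array([f"ID{j}" for j in range(n_genes)], dtype=object),
        gene_symbols=np.array(symbols, dtype=object),
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def make_matrix():
    return toy_matrix
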