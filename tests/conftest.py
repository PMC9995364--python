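import numpy as np
import pytest
import scipy.sparse as sp

import amlsc
from amlsc import syndata
from amlsc.readio import CountMatrix


@pytest.fixture(scope="session")
def small_config():
    return amlsc.SynthConfig(seed=11, n_cells=300, n_patients=80)


@pytest.fixture(scope="session")
def default_counts():
    """One 2000-cell planted count matrix shared across tests."""
    cfg = amlsc.SynthConfig(seed=5)
    matrix, truth = syndata.gen_counts(cfg)
    return cfg, matrix, truth


def make_count_matrix(counts, gene_ids=None, cell_ids=None, meta=None):
    """Small dense-matrix helper for hand-built fixtures."""
    counts = np.asarray(counts)
    genes = gene_ids or [f"g{i}" for i in range(counts.shape[0])]
    cells = cell_ids or [f"c{i}" for i in range(counts.shape[1])]
    kwargs = {} if meta is None else {"cell_meta": meta}
    return CountMatrix(sp.csr_matrix(counts), genes, cells, **kwargs)
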