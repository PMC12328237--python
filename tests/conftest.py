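import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from atlasstats.io import CELL_COLUMNS, ExpressionMatrix


def make_cells(cell_types, tissue="tissue0", individual="L1", method="droplet",
               compartment="other"):
    """Cell-annotation frame with one row per entry of ``cell_types``."""
    rows = [
        {
            "cell_id": f"c{i:04d}",
            "cell_type": ct,
            "tissue": tissue,
            "individual": individual,
            "compartment": compartment,
            "method": method,
        }
        for i, ct in enumerate(cell_types)
    ]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def make_expression(counts, cell_types, genes=None, **kw):
    counts = np.asarray(counts)
    genes = genes or [f"g{j}" for j in range(counts.shape[1])]
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts), cells=make_cells(cell_types, **kw), genes=genes
    )


@pytest.fixture
def tiny_expression():
    """3 cells x 2 genes with distinct entries."""
    return make_expression([[1, 0], [0, 3], [2, 5]], ["a", "a", "b"])
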