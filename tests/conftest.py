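import numpy as np
import pandas as pd
import pytest

from lincscope.io import SignatureMatrix


@pytest.fixture
def toy_meta() -> pd.DataFrame:
    """Six signatures over two cell lines, mixed categories."""
    return pd.DataFrame(
        {
            "sig_id": [f"S{i}" for i in range(6)],
            "cell_id": ["A", "A", "A", "B", "B", "A"],
            "pert_id": ["cmp1", "cmp1", "cmp2", "cmp1", "veh", "sh1"],
            "pert_iname": ["drug1", "drug1", "drug2", "drug1", "DMSO", "shGENE"],
            "pert_category": [
                "compound",
                "compound",
                "compound",
                "compound",
                "control",
                "shRNA",
            ],
            "dose_um": [1.0, 10.0, 5.0, 0.5, np.nan, np.nan],
            "time_h": [6.0, 24.0, 6.0, 24.0, 6.0, 96.0],
            "n_replicates": [3, 3, 5, 9, 27, 2],
        }
    )


@pytest.fixture
def small_matrix() -> SignatureMatrix:
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(10)]
    sigs = [f"S{i}" for i in range(4)]
    return SignatureMatrix(gene_ids=genes, sig_ids=sigs, z=rng.normal(size=(10, 4)))
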