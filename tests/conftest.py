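import numpy as np
import pandas as pd
import pytest

from pancanstrat import ExpressionMatrix, SampleSheet
from pancanstrat.data_io import SCALE_TPM


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


def make_matrix(values, gene_ids=None, sample_ids=None, scale=SCALE_TPM):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i + 1}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale
    )


def make_sheet(conditions, sites, sample_ids=None):
    sample_ids = sample_ids or [f"S{i + 1}" for i in range(len(conditions))]
    return SampleSheet(
        pd.DataFrame(
            {"condition": conditions, "primary_site": sites, "study": "t"},
            index=pd.Index(sample_ids, name="sample"),
        )
    )


@pytest.fixture
def tiny_pair():
    """2 sites x (2 tumours + 2 normals) x 3 genes on the TPM+1 scale."""
    genes = ["G1", "G2", "G3"]
    tumour = make_matrix(
        [[2.0, 4.0, 6.0, 8.0], [3.0, 3.0, 9.0, 9.0], [1.0, 2.0, 1.0, 2.0]],
        gene_ids=genes,
        sample_ids=["T1", "T2", "T3", "T4"],
    )
    normal = make_matrix(
        [[2.0, 4.0, 2.0, 6.0], [3.0, 3.0, 6.0, 6.0], [1.0, 1.0, 2.0, 2.0]],
        gene_ids=genes,
        sample_ids=["N1", "N2", "N3", "N4"],
    )
    sheet = make_sheet(
        ["tumour"] * 4 + ["normal"] * 4,
        ["A", "A", "B", "B"] * 2,
        sample_ids=["T1", "T2", "T3", "T4", "N1", "N2", "N3", "N4"],
    )
    return tumour, normal, sheet
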