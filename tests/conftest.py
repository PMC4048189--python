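import numpy as np
import pandas as pd
import pytest

from mitoscreen import ExpressionDataset, GeneMatrix


def make_dataset(values, groups, dataset_id="ds1", probes=None, samples=None, pairing=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=probes, columns=samples),
        sample_group=pd.Series(groups, index=samples),
        pairing=pairing or {},
    )


def make_gene_matrix(values, groups, genes=None, samples=None, dataset_id="ds1",
                     pairing=None, normalized=False):
    values = np.asarray(values, dtype=float)
    genes = genes or list(range(1, values.shape[0] + 1))
    samples = samples or [f"s{j+1}" for j in range(values.shape[1])]
    return GeneMatrix(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=pd.Index(genes, name="entrez_id"),
                            columns=samples),
        sample_group=pd.Series(groups, index=samples),
        pairing=pairing or {},
        normalized=normalized,
    )


@pytest.fixture
def small_dataset():
    """3 probes x 4 samples, 2 tumors and 2 normal livers."""
    return make_dataset(
        [[4.0, 6.0, 3.0, 3.0],
         [6.0, 8.0, 3.0, 5.0],
         [1.0, 2.0, 1.5, 1.5]],
        ["tumor", "tumor", "normal_liver", "normal_liver"],
    )


def write_tsvs(tmp_path, ds):
    from mitoscreen import write_expression_dataset
    m = tmp_path / f"{ds.dataset_id}_matrix.tsv"
    d = tmp_path / f"{ds.dataset_id}_meta.tsv"
    write_expression_dataset(ds, m, d)
    return m, d
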