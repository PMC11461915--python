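import numpy as np
import pandas as pd
import pytest

from jivebatch.io_preprocess import BatchCollection


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_collection(
    matrices, value_space="counts", cell_types=None, gene_ids=None, batch_labels=None
):
    """Build a small BatchCollection from raw arrays."""
    p = np.asarray(matrices[0]).shape[0]
    gene_ids = gene_ids or [f"g{i}" for i in range(p)]
    batch_labels = batch_labels or [f"b{i + 1}" for i in range(len(matrices))]
    cell_ids = [
        [f"{batch_labels[i]}_c{j}" for j in range(np.asarray(m).shape[1])]
        for i, m in enumerate(matrices)
    ]
    return BatchCollection(
        matrices=[np.asarray(m, dtype=float) for m in matrices],
        gene_ids=gene_ids,
        batch_labels=batch_labels,
        cell_ids=cell_ids,
        cell_types=cell_types,
        value_space=value_space,
    )


@pytest.fixture
def two_batch_counts(rng):
    """Two small random count matrices sharing 6 genes."""
    return make_collection(
        [rng.poisson(5.0, size=(6, 4)), rng.poisson(5.0, size=(6, 5))]
    )


def write_csv_batch(path, matrix, gene_ids, cell_ids):
    pd.DataFrame(matrix, index=gene_ids, columns=cell_ids).to_csv(path)


def write_labels(path, cell_ids_per_batch, batch_labels, cell_types=None):
    rows = []
    for b, cells in enumerate(cell_ids_per_batch):
        for j, c in enumerate(cells):
            row = {"cell_id": c, "batch": batch_labels[b]}
            if cell_types is not None:
                row["cell_type"] = cell_types[b][j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
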