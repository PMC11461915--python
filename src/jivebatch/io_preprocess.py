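"""Batch matrix I/O and preprocessing.

Matrices are stored gene x cell (genes on rows).  A :class:`BatchCollection`
holds one matrix per batch over a single shared gene axis, plus per-cell
batch and optional cell-type labels.  Preprocessing follows the standard
scRNA-seq workflow: library-size log-normalization and selection of the most
variable genes pooled across all batches.

Supported on-disk formats are Matrix Market (``.mtx``) with plain-text
sidecar files of row (gene) and column (cell) names, dense CSV (header row of
cell ids, first column gene ids), and a labels TSV with columns ``cell_id``,
``batch`` and optional ``cell_type``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

VALUE_SPACES = ("counts", "lognorm", "centered")


@dataclass
class BatchCollection:
    """An ordered set of gene x cell matrices sharing one gene axis.

    Parameters
    ----------
    matrices
        One dense ``(p, n_i)`` array per batch.
    gene_ids
        Length-``p`` list of gene identifiers shared by every matrix, in row
        order.
    batch_labels
        One distinct label per matrix.
    cell_ids
        Per-matrix lists of cell identifiers (length ``n_i`` each).
    cell_types
        Optional per-matrix lists of cell-type labels covering every cell.
    value_space
        One of ``counts``, ``lognorm`` or ``centered``.
    """

    matrices: list[np.ndarray]
    gene_ids: list[str]
    batch_labels: list[str]
    cell_ids: list[list[str]]
    cell_types: list[list[str]] | None = None
    value_space: str = "counts"

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        self.validate()

    def validate(self) -> None:
        if len(self.matrices) == 0:
            raise ValueError("BatchCollection requires at least one matrix")
        if self.value_space not in VALUE_SPACES:
            raise ValueError(f"unknown value_space {self.value_space!r}")
        p = len(self.gene_ids)
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene ids")
        for lab, m in zip(self.batch_labels, self.matrices):
            if m.ndim != 2 or m.shape[0] != p:
                raise ValueError(
                    f"batch {lab!r}: matrix has {m.shape[0]} rows, expected {p} genes"
                )
        if len(self.batch_labels) != len(self.matrices):
            raise ValueError("one batch label per matrix required")
        if len(set(self.batch_labels)) != len(self.batch_labels):
            raise ValueError("batch labels must be unique")
        if len(self.cell_ids) != len(self.matrices):
            raise ValueError("one cell-id list per matrix required")
        for lab, m, ids in zip(self.batch_labels, self.matrices, self.cell_ids):
            if len(ids) != m.shape[1]:
                raise ValueError(f"batch {lab!r}: cell id count != column count")
        if self.cell_types is not None:
            if len(self.cell_types) != len(self.matrices):
                raise ValueError("one cell-type list per matrix required")
            for lab, m, ct in zip(self.batch_labels, self.matrices, self.cell_types):
                if len(ct) != m.shape[1]:
                    raise ValueError(f"batch {lab!r}: cell types do not cover every cell")

    # ------------------------------------------------------------------
    @property
    def n_batches(self) -> int:
        return len(self.matrices)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> list[int]:
        return [m.shape[1] for m in self.matrices]

    @property
    def n_total_cells(self) -> int:
        return int(sum(self.n_cells))

    def stacked(self) -> np.ndarray:
        """Concatenate all batches into one ``(p, n)`` matrix in batch order."""
        return np.hstack(self.matrices)

    def batch_vector(self) -> np.ndarray:
        """Per-cell batch label, concatenated in batch order."""
        return np.concatenate(
            [np.repeat(lab, m.shape[1]) for lab, m in zip(self.batch_labels, self.matrices)]
        )

    def cell_type_vector(self) -> np.ndarray | None:
        if self.cell_types is None:
            return None
        return np.concatenate([np.asarray(ct, dtype=object) for ct in self.cell_types])

    def all_cell_ids(self) -> list[str]:
        return [c for ids in self.cell_ids for c in ids]


# ----------------------------------------------------------------------
# Readers / writers


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read one gene x cell matrix plus gene and cell names."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes = _read_names(path.with_suffix(".genes.txt"))
        cells = _read_names(path.with_suffix(".cells.txt"))
        if len(genes) != mat.shape[0] or len(cells) != mat.shape[1]:
            raise ValueError(f"{path}: sidecar name counts do not match matrix shape")
        return mat, genes, cells
    # dense CSV: header row of cell ids, first column gene ids
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]


def _read_names(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar name file {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def read_labels(labels_path: Path) -> pd.DataFrame:
    df = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"cell_id", "batch"}
    if not required.issubset(df.columns):
        raise ValueError(f"labels file must contain columns {sorted(required)}")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell ids in labels file")
    return df


def read_batches(
    matrix_paths: Sequence[str | Path],
    labels_path: str | Path,
    allow_unaligned: bool = False,
) -> BatchCollection:
    """Read per-batch matrices and a labels TSV into a :class:`BatchCollection`.

    Each matrix file holds one batch.  The labels file maps every cell id to
    its batch (and optionally a cell type); all cells of one matrix must
    belong to a single batch.  Gene lists must match across matrices unless
    ``allow_unaligned`` is set, in which case the result must be passed
    through :func:`align_genes` before any numeric workflow.
    """
    labels = read_labels(Path(labels_path))
    by_cell = labels.set_index("cell_id")
    has_types = "cell_type" in labels.columns

    matrices, gene_lists, cell_lists = [], [], []
    for pth in matrix_paths:
        m, genes, cells = _read_matrix(Path(pth))
        if len(set(genes)) != len(genes):
            raise ValueError(f"{pth}: duplicate gene ids within one matrix")
        matrices.append(m)
        gene_lists.append(genes)
        cell_lists.append(cells)

    unknown = set(c for cells in cell_lists for c in cells) - set(by_cell.index)
    if unknown:
        raise ValueError(f"cells missing from labels file: {sorted(unknown)[:5]} ...")

    batch_labels, cell_types = [], []
    for pth, cells in zip(matrix_paths, cell_lists):
        batches = set(by_cell.loc[cells, "batch"])
        if len(batches) != 1:
            raise ValueError(f"{pth}: cells map to multiple batches {sorted(batches)}")
        batch_labels.append(batches.pop())
        if has_types:
            cell_types.append([str(t) for t in by_cell.loc[cells, "cell_type"]])

    aligned = all(g == gene_lists[0] for g in gene_lists)
    if not aligned:
        if not allow_unaligned:
            raise ValueError(
                "gene lists differ across matrices; re-read with allow_unaligned=True "
                "and call align_genes() to restrict to the shared gene set"
            )
        return align_genes_raw(
            matrices,
            gene_lists,
            batch_labels,
            cell_lists,
            cell_types if has_types else None,
        )

    return BatchCollection(
        matrices=matrices,
        gene_ids=gene_lists[0],
        batch_labels=batch_labels,
        cell_ids=cell_lists,
        cell_types=cell_types if has_types else None,
        value_space="counts",
    )


def write_batches(collection: BatchCollection, out_dir: str | Path, fmt: str = "mtx") -> None:
    """Write each batch matrix plus sidecars and a labels TSV under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for b, (lab, m, cells) in enumerate(
        zip(collection.batch_labels, collection.matrices, collection.cell_ids)
    ):
        stem = out / f"batch_{b}"
        if fmt == "mtx":
            spio.mmwrite(str(stem) + ".mtx", sparse.coo_matrix(m))
            (out / f"batch_{b}.genes.txt").write_text("\n".join(collection.gene_ids) + "\n")
            (out / f"batch_{b}.cells.txt").write_text("\n".join(cells) + "\n")
        elif fmt == "csv":
            pd.DataFrame(m, index=collection.gene_ids, columns=cells).to_csv(
                str(stem) + ".csv"
            )
        else:
            raise ValueError(f"unknown format {fmt!r}")
        for j, c in enumerate(cells):
            rows.append(
                {
                    "cell_id": c,
                    "batch": lab,
                    **(
                        {"cell_type": collection.cell_types[b][j]}
                        if collection.cell_types is not None
                        else {}
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(out / "labels.tsv", sep="\t", index=False)


# ----------------------------------------------------------------------
# Gene alignment


def align_genes_raw(
    matrices: Sequence[np.ndarray],
    gene_lists: Sequence[Sequence[str]],
    batch_labels: Sequence[str],
    cell_ids: Sequence[Sequence[str]],
    cell_types: Sequence[Sequence[str]] | None = None,
    value_space: str = "counts",
) -> BatchCollection:
    """Restrict per-batch matrices with differing gene lists to their intersection.

    Rows are sorted into a single shared order (order of appearance in the
    first gene list); dropped-gene counts are logged.
    """
    shared = set(gene_lists[0])
    for g in gene_lists[1:]:
        shared &= set(g)
    if not shared:
        raise ValueError("gene sets have an empty intersection")
    order = [g for g in gene_lists[0] if g in shared]
    out = []
    for m, genes in zip(matrices, gene_lists):
        idx = {g: i for i, g in enumerate(genes)}
        dropped = len(genes) - len(order)
        if dropped:
            logger.info("align_genes: dropping %d genes from a batch", dropped)
        out.append(np.asarray(m, dtype=float)[[idx[g] for g in order], :])
    return BatchCollection(
        matrices=out,
        gene_ids=order,
        batch_labels=list(batch_labels),
        cell_ids=[list(c) for c in cell_ids],
        cell_types=[list(c) for c in cell_types] if cell_types is not None else None,
        value_space=value_space,
    )


def align_genes(collection: BatchCollection) -> BatchCollection:
    """Idempotent gene alignment for an already-shared gene axis."""
    # A validated BatchCollection always carries one shared gene list, so this
    # is the identity; it exists so pipelines can call it unconditionally.
    return collection


# ----------------------------------------------------------------------
# Normalization and gene selection


def log_normalize(collection: BatchCollection, scale_factor: float = 1e4) -> BatchCollection:
    """Library-size log-normalization: ``x -> ln(1 + scale_factor * x / L_c)``.

    ``L_c`` is the cell's library size (column sum).  Cells with zero library
    size are dropped with a warning.  Requires counts space and nonnegative
    entries.
    """
    if collection.value_space != "counts":
        raise ValueError("log_normalize expects a collection in counts space")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    matrices, cell_ids, cell_types = [], [], []
    for b, m in enumerate(collection.matrices):
        if np.any(m < 0):
            raise ValueError("negative entries in count matrix")
        lib = m.sum(axis=0)
        keep = lib > 0
        if not np.all(keep):
            warnings.warn(
                f"batch {collection.batch_labels[b]!r}: dropping "
                f"{int((~keep).sum())} cells with zero library size",
                stacklevel=2,
            )
        m = m[:, keep]
        lib = lib[keep]
        matrices.append(np.log1p(scale_factor * m / lib))
        cell_ids.append([c for c, k in zip(collection.cell_ids[b], keep) if k])
        if collection.cell_types is not None:
            cell_types.append([t for t, k in zip(collection.cell_types[b], keep) if k])
    return BatchCollection(
        matrices=matrices,
        gene_ids=list(collection.gene_ids),
        batch_labels=list(collection.batch_labels),
        cell_ids=cell_ids,
        cell_types=cell_types if collection.cell_types is not None else None,
        value_space="lognorm",
    )


def select_hvg(collection: BatchCollection, n_genes: int = 2000) -> BatchCollection:
    """Keep the ``n_genes`` genes with largest variance pooled over all cells.

    Variance is the plain per-gene variance of the (log-normalized) values
    across every cell of every batch; the original gene order is preserved
    among the kept genes.
    """
    if collection.value_space != "lognorm":
        raise ValueError("select_hvg expects log-normalized values")
    p = collection.n_genes
    if n_genes > p:
        raise ValueError(f"n_genes={n_genes} exceeds the {p} available genes")
    pooled = collection.stacked()
    var = pooled.var(axis=1, ddof=1) if pooled.shape[1] > 1 else pooled.var(axis=1)
    # top-n by variance, ties broken by original order, kept rows stay ordered
    keep = np.sort(np.argsort(-var, kind="stable")[:n_genes])
    return BatchCollection(
        matrices=[m[keep, :] for m in collection.matrices],
        gene_ids=[collection.gene_ids[i] for i in keep],
        batch_labels=list(collection.batch_labels),
        cell_ids=[list(c) for c in collection.cell_ids],
        cell_types=(
            [list(c) for c in collection.cell_types]
            if collection.cell_types is not None
            else None
        ),
        value_space="lognorm",
    )


def with_value_space(collection: BatchCollection, value_space: str) -> BatchCollection:
    """Return a shallow copy tagged with a different value space."""
    return replace(collection, value_space=value_space)
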