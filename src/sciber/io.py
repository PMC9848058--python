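"""Reading and writing expression matrices and cell metadata.

Two on-disk layouts are supported:

* Matrix Market: a directory with ``matrix.mtx`` (genes x cells),
  ``genes.tsv`` (one gene id per line) and ``barcodes.tsv`` (one cell id
  per line) — the common exchange layout for single-cell matrices.
* Dense CSV/TSV: genes as rows, a header row of cell ids, the first
  column holding gene ids.

Metadata is a TSV with columns ``cell_id``, ``batch`` and (optionally,
required only for evaluation) ``cell_type``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import ExpressionMatrix
from .projection import CorrectedMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
]


def _read_mtx_dir(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    mat = scipy.io.mmread(str(path / "matrix.mtx"))
    if sp.issparse(mat):
        mat = mat.toarray()
    genes = (path / "genes.tsv").read_text().split()
    cells = (path / "barcodes.tsv").read_text().split()
    return genes, cells, np.asarray(mat, dtype=np.float64)


def _read_dense(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return (
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=np.float64),
    )


def read_expression(
    path: str | Path,
    batch_id: str | None = None,
    allow_negative: bool = False,
) -> ExpressionMatrix | CorrectedMatrix:
    """Read a gene x cell matrix from an MTX directory or a CSV/TSV file.

    Corrected output may contain negative values (the linear projection
    can undershoot zero); pass `allow_negative=True` to read such files —
    they come back as a `CorrectedMatrix`.
    """
    path = Path(path)
    if batch_id is None:
        batch_id = path.stem if path.is_file() else path.name
    if path.is_dir():
        reader = _read_mtx_dir
    elif path.suffix.lower() in (".csv", ".tsv", ".txt"):
        reader = _read_dense
    else:
        raise ValueError(f"unrecognized expression input: {path}")
    genes, cells, values = reader(path)
    if allow_negative:
        return CorrectedMatrix(values, genes, cells, batch_id)
    return ExpressionMatrix(values, genes, cells, batch_id)


def write_expression(
    matrix: ExpressionMatrix | CorrectedMatrix,
    path: str | Path,
    fmt: str = "mtx",
) -> Path:
    """Write a matrix as an MTX directory (`fmt="mtx"`) or CSV file.

    For "mtx" `path` is a directory that will hold matrix.mtx,
    genes.tsv and barcodes.tsv; for "csv" it is the output file.
    """
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(matrix.values))
        (path / "genes.tsv").write_text("\n".join(matrix.gene_ids) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
        return path
    if fmt == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            matrix.values, index=matrix.gene_ids, columns=matrix.cell_ids
        ).to_csv(path)
        return path
    raise ValueError(f"unknown format {fmt!r} (expected 'mtx' or 'csv')")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cell metadata TSV (cell_id, batch[, cell_type])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "batch"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if df["cell_id"].duplicated().any():
        raise ValueError("metadata cell_id values must be unique")
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path
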