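"""Core in-memory container for one batch of log-expression data.

Expression is stored gene x cell (genes as rows), the orientation used by
most single-cell exchange formats.  All batches participating in one
integration run must share an identical, identically ordered gene panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative log-expression values.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_cells)
        Finite, non-negative log-normalized expression.
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    cell_ids : sequence of str
        Cell identifiers, unique within the batch, one per column.
    batch_id : str
        Label of the batch this matrix belongs to.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    batch_id: str = "batch"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x cell matrix")
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} gene_ids for {p} matrix rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell_ids for {n} matrix columns"
            )
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids must be unique within a batch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if np.any(self.values < 0):
            raise ValueError("log-expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to `genes`, keeping their order as given.

        Every requested gene must exist in the panel.
        """
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in panel: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            values=self.values[rows, :].copy(),
            gene_ids=list(genes),
            cell_ids=list(self.cell_ids),
            batch_id=self.batch_id,
        )

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
        )


def check_shared_panel(batches: Sequence[ExpressionMatrix]) -> list[str]:
    """Verify all batches carry the same ordered gene panel; return it."""
    if not batches:
        raise ValueError("no batches given")
    panel = batches[0].gene_ids
    for b in batches[1:]:
        if b.gene_ids != panel:
            raise ValueError(
                f"batch {b.batch_id!r} gene panel differs from "
                f"batch {batches[0].batch_id!r}"
            )
    return list(panel)
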