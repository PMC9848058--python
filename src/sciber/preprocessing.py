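"""Depth normalization, log transform and highly-variable-gene selection.

The integration method assumes its input is already depth-normalized and
log-transformed; this module produces such input from raw counts and,
optionally, restricts the gene panel to the per-batch union of highly
variable genes (HVGs).  Pre-normalized data may skip this module entirely.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .matrix import ExpressionMatrix, check_shared_panel

__all__ = ["normalize_and_log", "select_hvg_union", "subset_gene_panel"]

DEFAULT_SCALE = 10_000.0
DEFAULT_HVG = 2000


def normalize_and_log(
    counts,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
    batch_id: str = "batch",
    scale: float = DEFAULT_SCALE,
) -> ExpressionMatrix:
    """Depth-normalize counts per cell and apply log(1 + x).

    Each cell (column) is scaled so its counts sum to `scale` before the
    log transform: value(i, j) = log(1 + scale * count(i, j) / depth(j)).
    The natural log with pseudocount 1 is used.

    Parameters
    ----------
    counts : array-like or sparse, shape (n_genes, n_cells)
        Non-negative raw counts.
    scale : float
        Per-cell library size after normalization (default 10 000,
        the common counts-per-10k convention).

    Raises
    ------
    ValueError
        If a cell has an all-zero count column (its depth is undefined);
        the error names the offending cell.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if sp.issparse(counts):
        counts = np.asarray(counts.todense(), dtype=np.float64)
    else:
        counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D gene x cell matrix")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    depth = counts.sum(axis=0)
    zero = np.flatnonzero(depth == 0)
    if zero.size:
        bad = [str(cell_ids[i]) for i in zero[:5]]
        raise ValueError(
            f"cells with all-zero counts cannot be depth-normalized: {bad}"
        )
    values = np.log1p(scale * counts / depth[np.newaxis, :])
    return ExpressionMatrix(values, list(gene_ids), list(cell_ids), batch_id)


def _variance_ranking(X: ExpressionMatrix) -> np.ndarray:
    """Gene indices ranked by descending variance, stable in panel order."""
    var = X.values.var(axis=1)
    return np.argsort(-var, kind="stable")


def select_hvg_union(
    batches: Sequence[ExpressionMatrix], m: int = DEFAULT_HVG
) -> list[str]:
    """Union, over batches, of each batch's top-`m` most variable genes.

    The dispersion statistic is the per-gene variance of log-normalized
    expression within the batch.  Genes not in the top `m` of any batch are
    discarded.  The returned list preserves the input panel order.
    """
    if m <= 0:
        raise ValueError("m must be a positive integer")
    panel = check_shared_panel(batches)
    m = min(m, len(panel))
    keep = np.zeros(len(panel), dtype=bool)
    for batch in batches:
        keep[_variance_ranking(batch)[:m]] = True
    return [g for g, k in zip(panel, keep) if k]


def subset_gene_panel(
    batches: Sequence[ExpressionMatrix], genes: Sequence[str]
) -> list[ExpressionMatrix]:
    """Restrict every batch to `genes`, preserving the given order."""
    check_shared_panel(batches)
    return [b.subset_genes(genes) for b in batches]
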