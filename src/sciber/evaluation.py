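"""Local Inverse Simpson Index (LISI) evaluation of integrated data.

cLISI — LISI computed on cell-type labels — measures local cell-type
purity: for each cell, Gaussian kernel weights over its nearest neighbors
are calibrated so their entropy equals log(perplexity), the weights are
aggregated into label proportions q(t), and the score is the inverse
Simpson index 1 / sum_t q(t)^2, the effective number of labels in the
neighborhood.  A cLISI of 1.0 means every neighborhood is a single cell
type (perfect purity, to be minimized); LISI on batch labels measures
batch mixing (to be maximized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix
from .projection import CorrectedMatrix

__all__ = ["CLISIResult", "lisi", "evaluate_correction"]

DEFAULT_PERPLEXITY = 30.0
DEFAULT_PCS = 20
_ENTROPY_TOL = 1e-5
_MAX_BISECT = 50


@dataclass
class CLISIResult:
    """Per-cell LISI scores under one labeling, plus summaries.

    `mean` is the arithmetic mean over all cells ("overall" score);
    `per_label_mean` averages per-cell scores within each label first
    (the per-cell-type convention).  Scores lie in [1, n_labels].
    """

    per_cell: np.ndarray
    mean: float
    perplexity: float
    label_kind: str
    per_label_mean: dict[str, float]


def _calibrate_weights(sq_dists: np.ndarray, log_perp: float) -> np.ndarray:
    """Gaussian weights over one cell's neighbors with entropy log_perp.

    Binary search on the kernel precision (t-SNE convention): start at
    beta = 1, double/halve to bracket, then bisect; at most 50 iterations
    or entropy within 1e-5 of the target.
    """
    beta, beta_min, beta_max = 1.0, -np.inf, np.inf
    d = sq_dists - sq_dists.min()  # stabilize the exponentials
    for _ in range(_MAX_BISECT):
        w = np.exp(-d * beta)
        s = w.sum()
        # Shannon entropy of the normalized weights
        H = np.log(s) + beta * float((d * w).sum()) / s
        if abs(H - log_perp) < _ENTROPY_TOL:
            break
        if H > log_perp:  # too flat -> sharpen
            beta_min = beta
            beta = beta * 2.0 if np.isinf(beta_max) else (beta + beta_max) / 2.0
        else:
            beta_max = beta
            beta = beta / 2.0 if np.isinf(beta_min) else (beta + beta_min) / 2.0
    w = np.exp(-d * beta)
    return w / w.sum()


def lisi(
    embedding: np.ndarray,
    labels: Sequence,
    perplexity: float = DEFAULT_PERPLEXITY,
    label_kind: str = "cell_type",
) -> CLISIResult:
    """Per-cell local inverse Simpson index of `labels` in `embedding`.

    Parameters
    ----------
    embedding : ndarray of shape (n_cells, d)
        Coordinates used for the neighbor search (e.g. principal
        components of log-expression).
    labels : sequence of length n_cells
        Categorical label per cell (cell type or batch).
    perplexity : float
        Effective neighborhood size; 3 * perplexity nearest neighbors are
        used, which must be fewer than the number of cells.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim == 1:
        emb = emb[:, np.newaxis]
    n = emb.shape[0]
    labels = np.asarray([str(l) for l in labels])
    if labels.shape[0] != n:
        raise ValueError("one label per cell required")
    if n < 2:
        raise ValueError("LISI needs at least 2 cells")
    if perplexity <= 0:
        raise ValueError("perplexity must be positive")
    n_neighbors = int(np.floor(3 * perplexity))
    if n_neighbors >= n:
        raise ValueError(
            f"3*perplexity = {n_neighbors} neighbors requested but only "
            f"{n} cells present; lower the perplexity"
        )

    categories, codes = np.unique(labels, return_inverse=True)
    n_labels = categories.size
    if n_labels == 1:
        per_cell = np.ones(n)
        return CLISIResult(per_cell, 1.0, perplexity, label_kind,
                           {str(categories[0]): 1.0})

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(emb)
    dist, idx = nn.kneighbors(emb)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    log_perp = float(np.log(perplexity))
    per_cell = np.empty(n)
    for i in range(n):
        w = _calibrate_weights(dist[i] ** 2, log_perp)
        q = np.bincount(codes[idx[i]], weights=w, minlength=n_labels)
        per_cell[i] = 1.0 / float((q**2).sum())

    assert np.all(per_cell <= n_labels + 1e-9), "LISI exceeded label count"
    per_label = {
        str(cat): float(per_cell[codes == t].mean())
        for t, cat in enumerate(categories)
    }
    return CLISIResult(
        per_cell=per_cell,
        mean=float(per_cell.mean()),
        perplexity=perplexity,
        label_kind=label_kind,
        per_label_mean=per_label,
    )


def _stack_batches(
    matrices: Sequence[ExpressionMatrix | CorrectedMatrix],
) -> tuple[np.ndarray, list[str]]:
    panel = matrices[0].gene_ids
    cols, cells = [], []
    for m in matrices:
        if m.gene_ids != panel:
            raise ValueError("all matrices must share the gene panel")
        cols.append(m.values)
        cells.extend(m.cell_ids)
    return np.hstack(cols).T, cells  # cells x genes


def evaluate_correction(
    matrices: Sequence[ExpressionMatrix | CorrectedMatrix],
    cell_types: dict[str, str] | Sequence,
    batches: dict[str, str] | Sequence,
    d: int = DEFAULT_PCS,
    perplexity: float = DEFAULT_PERPLEXITY,
    random_state: int = 0,
) -> tuple[CLISIResult, CLISIResult]:
    """cLISI (cell type) and LISI (batch) of concatenated batches.

    Concatenates the given matrices (typically the untouched reference
    plus corrected queries), reduces to `d` principal components, and
    scores both labelings.  The cell-type score is to be minimized, the
    batch score to be maximized.  Labels may be given as dicts keyed by
    cell id or as sequences aligned with the concatenated cell order.
    `d=0` skips PCA and evaluates in raw gene space.
    """
    X, cells = _stack_batches(matrices)

    def resolve(lab, name):
        if isinstance(lab, dict):
            missing = [c for c in cells if c not in lab]
            if missing:
                raise ValueError(f"missing {name} labels for cells {missing[:5]}")
            return [lab[c] for c in cells]
        lab = list(lab)
        if len(lab) != len(cells):
            raise ValueError(f"{name} labels do not align with cells")
        return lab

    type_labels = resolve(cell_types, "cell_type")
    batch_labels = resolve(batches, "batch")

    if d and d > 0:
        n_comp = min(d, X.shape[0] - 1, X.shape[1])
        emb = PCA(n_components=n_comp, random_state=random_state).fit_transform(X)
    else:
        emb = X
    clisi = lisi(emb, type_labels, perplexity, label_kind="cell_type")
    blisi = lisi(emb, batch_labels, perplexity, label_kind="batch")
    return clisi, blisi
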