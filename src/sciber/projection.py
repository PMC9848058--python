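"""Step 4: linear projection of a query batch onto the reference.

Every query cell x is decomposed by least squares on the centroids of the
query clusters that have a putative match, beta = argmin ||x - Xc_q b||,
and re-synthesized from the matched reference centroids: x_corrected =
Xc_ref beta.  The decomposition is applied to all cells of the query
batch, including cells in clusters without a putative match — those are
handled by interpolation/extrapolation of the linear map.  The reference
batch itself is never passed through this step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .clustering import ClusterAssignment
from .matching import MatchedPair
from .matrix import ExpressionMatrix

__all__ = [
    "ProjectionModel",
    "CorrectedMatrix",
    "centroid_pair_matrices",
    "project_batch",
]


@dataclass
class ProjectionModel:
    """Centroid basis pair and fitted coefficients for one query batch.

    Column j of `Xc_ref` is the centroid of the reference cluster
    putatively matched to the query cluster whose centroid is column j of
    `Xc_query`.  `beta` holds the per-cell least-squares coefficients.
    """

    Xc_query: np.ndarray  # (p, m)
    Xc_ref: np.ndarray  # (p, m)
    beta: np.ndarray  # (m, n_cells)
    m: int


@dataclass
class CorrectedMatrix:
    """Batch-effect corrected expression of one query batch.

    Same genes and cells, in the same order, as the input query batch.
    Values may be negative (a linear combination can undershoot zero)
    unless clamping was requested.
    """

    values: np.ndarray  # (p, n_cells)
    gene_ids: list[str]
    cell_ids: list[str]
    query_batch: str


def centroid_pair_matrices(
    query_assign: ClusterAssignment,
    ref_assign: ClusterAssignment,
    putative: list[MatchedPair],
) -> tuple[np.ndarray, np.ndarray]:
    """Build (Xc_query, Xc_ref), one column per putative pair, in pair order.

    A reference cluster matched by k query clusters contributes its
    centroid k times; column multiplicity follows the pair list.
    """
    pairs = [pr for pr in putative if pr.putative]
    if not pairs:
        raise ValueError("no putative matches; consider raising omega")
    Xc_query = np.column_stack(
        [query_assign.centroid_of(pr.query_cluster) for pr in pairs]
    )
    Xc_ref = np.column_stack(
        [ref_assign.centroid_of(pr.ref_cluster) for pr in pairs]
    )
    return Xc_query, Xc_ref


def project_batch(
    X_query: ExpressionMatrix,
    Xc_query: np.ndarray,
    Xc_ref: np.ndarray,
    clamp_nonnegative: bool = False,
    return_model: bool = False,
):
    """Project all cells of a query batch onto the reference centroid space.

    Computes beta minimizing ||X - Xc_query beta|| column-wise and returns
    Xc_ref @ beta as a `CorrectedMatrix`.  A rank-deficient centroid basis
    (possible when a reference cluster is matched repeatedly) is handled
    by the minimum-norm least-squares solution rather than the explicit
    normal-equations inverse.

    With `clamp_nonnegative=True` negative corrected values are clipped at
    zero; default off, preserving the linear map exactly.
    """
    Xc_query = np.asarray(Xc_query, dtype=np.float64)
    Xc_ref = np.asarray(Xc_ref, dtype=np.float64)
    if Xc_query.ndim != 2 or Xc_ref.ndim != 2:
        raise ValueError("centroid matrices must be 2-D")
    p, m = Xc_query.shape
    if m < 1:
        raise ValueError("need at least one putative centroid pair")
    if Xc_ref.shape != (X_query.n_genes, m):
        raise ValueError("Xc_ref shape does not match Xc_query / query batch")
    if p != X_query.n_genes:
        raise ValueError(
            f"centroid rows ({p}) != query gene panel ({X_query.n_genes})"
        )
    if not np.any(Xc_query):
        raise ValueError("query centroid matrix is identically zero")

    # min-norm least squares via SVD (lapack gelsd)
    beta, *_ = scipy.linalg.lstsq(Xc_query, X_query.values, lapack_driver="gelsd")
    corrected = Xc_ref @ beta
    if clamp_nonnegative:
        corrected = np.maximum(corrected, 0.0)
    result = CorrectedMatrix(
        values=corrected,
        gene_ids=list(X_query.gene_ids),
        cell_ids=list(X_query.cell_ids),
        query_batch=X_query.batch_id,
    )
    if return_model:
        return result, ProjectionModel(Xc_query, Xc_ref, beta, m)
    return result
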