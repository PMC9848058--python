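"""Step 2: marker-gene identification per cluster.

For each cluster, every gene is tested with a Welch two-sample t-test of
the cluster's cells against all other cells of the same batch.  The h
genes up-regulated in the cluster with the smallest p-values are its
"marker genes".  Only ranks matter downstream (the matching step counts
shared markers), so no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clustering import ClusterAssignment
from .matrix import ExpressionMatrix

__all__ = ["MarkerSet", "two_sample_t", "marker_genes", "markers_for_batch"]

DEFAULT_H = 75
MIN_GROUP = 3  # smallest testable cluster (and complement)


@dataclass
class MarkerSet:
    """Top up-regulated genes of one cluster, sorted by p-value ascending.

    An "untestable" set (cluster or complement too small) is empty and is
    excluded from cluster matching.
    """

    batch_id: str
    cluster_id: int
    genes: list[str]
    p_values: list[float]
    h: int
    untestable: bool = False

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.p_values):
            raise ValueError("genes and p_values must align")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("marker genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def testable(self) -> bool:
        return not self.untestable


def two_sample_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns (t, p) with t = (mean_a - mean_b) / sqrt(s2a/na + s2b/nb) and
    the p-value from a t distribution with Welch-Satterthwaite degrees of
    freedom.  Each group needs at least two values.  If both sample
    variances are zero the statistic is undefined; by convention equal
    means give (0.0, 1.0) and unequal means (+/-inf, 0.0).
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        diff = a.mean() - b.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _welch_vectorized(
    X: np.ndarray, in_cluster: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene Welch test of cluster vs rest; returns (mean_diff, t, p)."""
    A = X[:, in_cluster]
    B = X[:, ~in_cluster]
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    diff = ma - mb
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate genes: zero variance in both groups
    flat = se2 == 0.0
    t[flat & (diff == 0.0)] = 0.0
    p[flat & (diff == 0.0)] = 1.0
    t[flat & (diff != 0.0)] = np.sign(diff[flat & (diff != 0.0)]) * np.inf
    p[flat & (diff != 0.0)] = 0.0
    return diff, t, p


def marker_genes(
    X: ExpressionMatrix,
    assignment: ClusterAssignment,
    cluster_id: int,
    h: int = DEFAULT_H,
) -> MarkerSet:
    """Top-`h` up-regulated genes of one cluster vs the rest of its batch.

    Genes are restricted to those with a strictly positive mean difference
    (cluster mean above the rest), then ranked by two-sided Welch p-value
    ascending; ties broken by larger mean difference, then by gene order.
    Fewer than h up-regulated genes yield a shorter list, never padding.

    A cluster with fewer than three cells, or whose complement has fewer
    than three cells, is untestable and yields an empty, flagged set.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if h > X.n_genes:
        raise ValueError(f"h={h} exceeds the {X.n_genes}-gene panel")
    if assignment.batch_id != X.batch_id:
        raise ValueError("assignment belongs to a different batch")
    in_cluster = assignment.labels == cluster_id
    n_in = int(in_cluster.sum())
    if n_in == 0:
        raise KeyError(f"cluster {cluster_id} has no cells")
    if n_in < MIN_GROUP or (X.n_cells - n_in) < MIN_GROUP:
        return MarkerSet(X.batch_id, cluster_id, [], [], h, untestable=True)

    diff, _t, p = _welch_vectorized(X.values, in_cluster)
    up = np.flatnonzero(diff > 0)
    # sort by (p asc, mean-diff desc, gene order) for determinism
    order = up[np.lexsort((up, -diff[up], p[up]))]
    top = order[: min(h, order.size)]
    return MarkerSet(
        batch_id=X.batch_id,
        cluster_id=cluster_id,
        genes=[X.gene_ids[i] for i in top],
        p_values=[float(p[i]) for i in top],
        h=h,
    )


def markers_for_batch(
    X: ExpressionMatrix, assignment: ClusterAssignment, h: int = DEFAULT_H
) -> list[MarkerSet]:
    """Marker sets for every realized cluster of a batch, in label order."""
    return [
        marker_genes(X, assignment, k, h=h) for k in range(1, assignment.K + 1)
    ]
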