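"""Step 1: per-batch K-means over-clustering.

Each batch is clustered independently — never pooled with another batch,
since clustering on pooled data would itself be confounded by batch
effects.  K is deliberately chosen much larger than the expected number of
cell types ("over-clustering"): large types split into several tight
clusters, each contributing a centroid to the projection basis, while
outliers end up in small clusters that the matching step can discard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

__all__ = ["ClusterAssignment", "default_k", "cluster_batch"]

SMALL_CLUSTER_SIZE = 3  # clusters below this are kept but flagged


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels (1..K) and per-cluster centroids.

    `centroids[:, k-1]` is the mean expression vector of the cells with
    label k.  Only non-empty clusters are represented; `K` is the realized
    number of clusters.  `small_clusters` lists labels with fewer than
    three cells — they are clustered normally but downstream marker
    testing refuses them.
    """

    batch_id: str
    labels: np.ndarray  # (n_cells,), ints in 1..K
    centroids: np.ndarray  # (n_genes, K)
    K: int
    seed: int
    small_clusters: list[int] = field(default_factory=list)

    def cluster_sizes(self) -> dict[int, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def centroid_of(self, cluster_id: int) -> np.ndarray:
        if not 1 <= cluster_id <= self.K:
            raise KeyError(f"cluster {cluster_id} not in 1..{self.K}")
        return self.centroids[:, cluster_id - 1]


def default_k(n0: int, multiplier: float = 1.0) -> int:
    """Default number of clusters: round(multiplier * sqrt(n0)), at least 2.

    n0 is the number of cells in the reference batch.  The square-root
    rule gives the over-clustering regime the method relies on without
    degenerating to one cell per cluster.
    """
    if n0 < 4:
        raise ValueError("need at least 4 reference cells to cluster")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    # round half up, deterministically
    return max(2, int(np.floor(multiplier * np.sqrt(n0) + 0.5)))


def cluster_batch(X: ExpressionMatrix, K: int, seed: int = 0) -> ClusterAssignment:
    """K-means the cells of one batch into K clusters.

    Deterministic given (X, K, seed): k-means++ initialization with 10
    restarts and at most 300 iterations, seeded.  Empty clusters (rare at
    convergence) are dropped and labels renumbered to 1..K'.  Centroids
    are recomputed as exact means of the assigned cells.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > X.n_cells:
        raise ValueError(
            f"K={K} exceeds the {X.n_cells} cells of batch {X.batch_id!r}"
        )
    if not np.all(np.isfinite(X.values)):
        raise ValueError("expression matrix contains non-finite values")

    cells = np.ascontiguousarray(X.values.T)  # cells x genes for sklearn
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=10,
        max_iter=300,
        random_state=seed,
    ).fit(cells)
    raw = km.labels_

    # drop empty clusters, relabel to 1..K'
    present = np.unique(raw)
    remap = {old: new for new, old in enumerate(present, start=1)}
    labels = np.array([remap[l] for l in raw], dtype=np.int64)
    realized = len(present)

    centroids = np.empty((X.n_genes, realized), dtype=np.float64)
    small: list[int] = []
    for k in range(1, realized + 1):
        members = labels == k
        centroids[:, k - 1] = X.values[:, members].mean(axis=1)
        if int(members.sum()) < SMALL_CLUSTER_SIZE:
            small.append(k)

    return ClusterAssignment(
        batch_id=X.batch_id,
        labels=labels,
        centroids=centroids,
        K=realized,
        seed=seed,
        small_clusters=small,
    )
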