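"""End-to-end orchestration: the SCIBER estimator and `run_sciber`.

The estimator follows the scikit-learn protocol: `fit` consumes the
reference batch (clusters it once and derives its marker sets — the
reference is never modified), and `transform` corrects one query batch
against the fitted reference.  Each query is processed independently, so
corrected output for a query depends only on (reference, that query,
parameters) — adding further batches later never changes earlier results.
"""

from __future__ import annotations

import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import cluster_batch, default_k
from .markers import DEFAULT_H, markers_for_batch
from .matching import DEFAULT_OMEGA, match_clusters, putative_matches
from .matrix import ExpressionMatrix
from .preprocessing import select_hvg_union, subset_gene_panel
from .projection import CorrectedMatrix, centroid_pair_matrices, project_batch

__all__ = ["SCIBER", "SciberConfig", "run_sciber"]

logger = logging.getLogger("sciber")

MIN_SHARED_GENES = 50


@dataclass
class SciberConfig:
    """Parameter bundle for one integration run.

    Defaults reproduce the method's stated defaults: K chosen
    automatically from the reference size (round(k_multiplier * sqrt(n0))),
    h = 75 marker genes per cluster, omega = 0.5 putative-match
    proportion.  `hvg_m` of None (or "skip") bypasses HVG selection for
    pre-processed input.
    """

    k: int | str = "auto"
    k_multiplier: float = 1.0
    h: int = DEFAULT_H
    omega: float = DEFAULT_OMEGA
    seed: int = 0
    hvg_m: int | str | None = None
    clamp_nonnegative: bool = False


def _query_seed(seed: int, batch_id: str) -> int:
    # content-addressed so each query's result is independent of the others
    return (int(seed) + zlib.crc32(batch_id.encode())) % (2**31)


class SCIBER(BaseEstimator):
    """Reference-based batch correction by cluster matching and projection.

    Four steps: (1) K-means over-clustering of each batch separately,
    (2) Welch-t marker genes per cluster, (3) query-to-reference cluster
    matching by marker overlap scored with a one-sided Fisher test, the
    omega fraction with smallest p-values kept as putative matches,
    (4) least-squares decomposition of every query cell on the putative
    query centroids, re-synthesized from the matched reference centroids.

    Parameters
    ----------
    k : int or "auto"
        Clusters per batch; "auto" uses round(k_multiplier * sqrt(n0))
        with n0 the reference cell count.
    k_multiplier : float
        Scale factor for the automatic K (sensitivity grid 0.8/1.0/1.2).
    h : int
        Marker genes per cluster (default 75).
    omega : float in (0, 1]
        Proportion of matched pairs kept as putative matches (default
        0.5); roughly the fraction of cells shared between batches.
    random_state : int
        Seeds the K-means runs; each query batch derives its own seed
        from (random_state, batch id).
    clamp_nonnegative : bool
        Clip negative corrected values at zero (default off).

    Attributes
    ----------
    ref_ : ExpressionMatrix
        The reference batch, held untouched.
    ref_assignment_ : ClusterAssignment
        Reference clustering, computed once and reused for every query.
    ref_markers_ : list of MarkerSet
        Marker sets of the reference clusters.
    K_ : int
        Realized number of reference clusters.

    Examples
    --------
    >>> model = SCIBER(omega=0.5, random_state=0).fit(reference)
    >>> corrected = model.transform(query)   # doctest: +SKIP
    """

    def __init__(
        self,
        k: int | str = "auto",
        k_multiplier: float = 1.0,
        h: int = DEFAULT_H,
        omega: float = DEFAULT_OMEGA,
        random_state: int = 0,
        clamp_nonnegative: bool = False,
    ):
        self.k = k
        self.k_multiplier = k_multiplier
        self.h = h
        self.omega = omega
        self.random_state = random_state
        self.clamp_nonnegative = clamp_nonnegative

    # -- helpers ---------------------------------------------------------
    def _coerce(self, X, batch_id: str) -> ExpressionMatrix:
        """Accept an ExpressionMatrix, or an (n_cells, n_genes) array in
        the scikit-learn orientation."""
        if isinstance(X, ExpressionMatrix):
            return X
        arr = np.asarray(X, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("expected a 2-D array of shape (cells, genes)")
        genes = [f"g{i}" for i in range(arr.shape[1])]
        cells = [f"{batch_id}_c{j}" for j in range(arr.shape[0])]
        return ExpressionMatrix(arr.T, genes, cells, batch_id)

    def _resolve_k(self, n_cells: int) -> int:
        if self.k == "auto":
            return min(default_k(n_cells, self.k_multiplier), n_cells)
        k = int(self.k)
        if k < 2:
            raise ValueError("k must be at least 2")
        return min(k, n_cells)

    # -- sklearn surface -------------------------------------------------
    def fit(self, X, y=None):
        """Cluster the reference batch and compute its marker sets."""
        ref = self._coerce(X, "reference")
        t0 = time.perf_counter()
        K = self._resolve_k(ref.n_cells)
        assignment = cluster_batch(ref, K, seed=int(self.random_state))
        marks = markers_for_batch(ref, assignment, h=self.h)
        self.ref_ = ref
        self.ref_assignment_ = assignment
        self.ref_markers_ = marks
        self.K_ = assignment.K
        self.n_features_in_ = ref.n_genes
        logger.info(
            "fit: reference %r, %d cells -> %d clusters (%d testable) "
            "in %.2fs",
            ref.batch_id, ref.n_cells, assignment.K,
            sum(m.testable for m in marks), time.perf_counter() - t0,
        )
        return self

    def transform(self, X):
        """Correct one query batch; returns a CorrectedMatrix (or an
        array if the input was an array)."""
        if not hasattr(self, "ref_assignment_"):
            raise RuntimeError("SCIBER instance is not fitted yet")
        was_array = not isinstance(X, ExpressionMatrix)
        query = self._coerce(X, "query")
        if query.gene_ids != self.ref_.gene_ids:
            raise ValueError(
                f"query batch {query.batch_id!r} gene panel differs from "
                "the reference; reconcile panels first (run_sciber does)"
            )
        t0 = time.perf_counter()
        if query is self.ref_:
            # self-integration: reuse the reference clustering so clusters
            # pair with themselves and the result is the least-squares fit
            # of the data onto its own putative centroids
            q_assign, q_marks = self.ref_assignment_, self.ref_markers_
        else:
            seed = _query_seed(int(self.random_state), query.batch_id)
            K = min(self._resolve_k(self.ref_.n_cells), query.n_cells)
            q_assign = cluster_batch(query, K, seed=seed)
            q_marks = markers_for_batch(query, q_assign, h=self.h)
        pairs = match_clusters(q_marks, self.ref_markers_, p=query.n_genes)
        flagged = putative_matches(pairs, omega=self.omega)
        Xc_q, Xc_r = centroid_pair_matrices(
            q_assign, self.ref_assignment_, flagged
        )
        corrected = project_batch(
            query, Xc_q, Xc_r, clamp_nonnegative=self.clamp_nonnegative
        )
        logger.info(
            "transform: query %r, %d cells, %d clusters, %d matched pairs "
            "(%d putative) in %.2fs",
            query.batch_id, query.n_cells, q_assign.K, len(pairs),
            sum(pr.putative for pr in flagged), time.perf_counter() - t0,
        )
        self.last_pairs_ = flagged
        self.last_query_assignment_ = q_assign
        if was_array:
            return corrected.values.T
        return corrected

    def fit_transform(self, X, y=None, **fit_params):
        """Fit on X as the reference and project X onto itself.

        Self-integration: with identical clusterings on both sides the
        result is the least-squares fit of the data onto its own putative
        centroids.
        """
        return self.fit(X, y).transform(X)


def _reconcile_panels(
    reference: ExpressionMatrix, queries: list[ExpressionMatrix]
) -> list[ExpressionMatrix]:
    batches = [reference, *queries]
    panels = [b.gene_ids for b in batches]
    if all(p == panels[0] for p in panels):
        return batches
    shared = set(panels[0])
    for p in panels[1:]:
        shared &= set(p)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared across batches "
            f"(< {MIN_SHARED_GENES}); refusing to integrate"
        )
    keep = [g for g in reference.gene_ids if g in shared]
    warnings.warn(
        f"batches disagree on gene panels; intersecting to {len(keep)} genes",
        UserWarning,
        stacklevel=3,
    )
    return [b.subset_genes(keep) for b in batches]


def run_sciber(
    reference: ExpressionMatrix,
    queries: list[ExpressionMatrix],
    config: SciberConfig | None = None,
) -> list[CorrectedMatrix]:
    """Integrate query batches onto the reference; returns corrected queries.

    The reference is clustered once and reused for every query; it is
    returned to the caller untouched (the function never copies or
    modifies it).  Optional HVG selection (config.hvg_m an integer)
    restricts all batches to the per-batch union of top-m variable genes
    before correction.
    """
    config = config or SciberConfig()
    if not queries:
        raise ValueError("need at least one query batch")
    reference, *queries = _reconcile_panels(reference, list(queries))

    if isinstance(config.hvg_m, int):
        panel = select_hvg_union([reference, *queries], m=config.hvg_m)
        reference, *queries = subset_gene_panel(
            [reference, *queries], panel
        )
        logger.info("HVG union panel: %d genes", len(panel))
    elif config.hvg_m not in (None, "skip"):
        raise ValueError("hvg_m must be a positive integer, None, or 'skip'")

    model = SCIBER(
        k=config.k,
        k_multiplier=config.k_multiplier,
        h=config.h,
        omega=config.omega,
        random_state=config.seed,
        clamp_nonnegative=config.clamp_nonnegative,
    ).fit(reference)
    return [model.transform(q) for q in queries]
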