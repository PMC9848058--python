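"""Step 3: cluster matching across batches by marker-gene overlap.

Each query cluster is paired with the reference cluster sharing the most
marker genes; the pair is scored with a one-sided Fisher's exact test on
the 2x2 gene-membership table over the shared panel.  Only the omega
proportion of pairs with the smallest p-values are kept as "putative
matches" — the rest typically correspond to query cell types absent from
the reference (or to outlier clusters) and must not drive the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .markers import MarkerSet

__all__ = [
    "MatchedPair",
    "overlap_table",
    "fisher_one_sided",
    "match_clusters",
    "putative_matches",
]

DEFAULT_OMEGA = 0.5


@dataclass
class MatchedPair:
    """A query cluster paired with its best-overlapping reference cluster."""

    query_batch: str
    query_cluster: int
    ref_cluster: int
    overlap: int
    table: tuple[int, int, int, int]  # (a, b, c, d); a == overlap
    p_value: float
    putative: bool = False


def overlap_table(
    query_markers: MarkerSet,
    ref_markers: MarkerSet,
    p: int,
    panel: set[str] | None = None,
) -> tuple[int, int, int, int]:
    """2x2 contingency table (a, b, c, d) of marker membership.

    a = shared markers, b = query-only, c = reference-only,
    d = p - a - b - c (genes in neither set), over a shared panel of p
    genes.  If `panel` is given, membership of every marker in it is
    checked.
    """
    q = set(query_markers.genes)
    r = set(ref_markers.genes)
    if panel is not None:
        stray = (q | r) - panel
        if stray:
            raise ValueError(f"marker genes not in panel: {sorted(stray)[:5]}")
    a = len(q & r)
    b = len(q) - a
    c = len(r) - a
    d = p - a - b - c
    if d < 0:
        raise ValueError("marker sets larger than the stated panel size")
    return a, b, c, d


def fisher_one_sided(table: tuple[int, int, int, int]) -> float:
    """One-sided (enrichment) Fisher's exact test p-value.

    For table (a, b, c, d): the hypergeometric upper tail P[X >= a] when
    drawing a+b genes from a panel of a+b+c+d containing a+c "successes".
    A one-sided test is used because only excess marker sharing — never
    depletion — is evidence that two clusters are the same cell type.
    """
    a, b, c, d = (int(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table entries must be non-negative")
    M = a + b + c + d  # panel size
    n = a + c  # reference markers
    N = a + b  # query markers (draws)
    if M == 0:
        return 1.0  # empty panel: the only table is the observed one
    return float(stats.hypergeom.sf(a - 1, M, n, N))


def match_clusters(
    query_markersets: list[MarkerSet],
    ref_markersets: list[MarkerSet],
    p: int,
) -> list[MatchedPair]:
    """Pair every testable query cluster with its best reference cluster.

    "Best" maximizes marker overlap; ties are broken by smaller Fisher
    p-value, then by lower reference cluster index.  The map is
    many-to-one: several query clusters may share a reference cluster.
    Untestable (empty) marker sets on either side yield no pair.
    """
    refs = [m for m in ref_markersets if m.testable and len(m) > 0]
    if not refs:
        raise ValueError("no testable reference clusters to match against")
    pairs: list[MatchedPair] = []
    for qm in query_markersets:
        if not qm.testable or len(qm) == 0:
            continue
        best: tuple[int, float, int] | None = None  # (-overlap, p, ref_idx)
        best_entry: tuple[int, int, tuple[int, int, int, int], float] | None = None
        for rm in refs:
            table = overlap_table(qm, rm, p)
            a = table[0]
            pval = fisher_one_sided(table)
            key = (-a, pval, rm.cluster_id)
            if best is None or key < best:
                best = key
                best_entry = (rm.cluster_id, a, table, pval)
        assert best_entry is not None
        ref_cluster, a, table, pval = best_entry
        pairs.append(
            MatchedPair(
                query_batch=qm.batch_id,
                query_cluster=qm.cluster_id,
                ref_cluster=ref_cluster,
                overlap=a,
                table=table,
                p_value=pval,
            )
        )
    return pairs


def putative_matches(
    pairs: list[MatchedPair], omega: float = DEFAULT_OMEGA
) -> list[MatchedPair]:
    """Flag the omega proportion of pairs with smallest p-values as putative.

    round(omega * n) pairs, half-up and at least 1, are marked putative.
    Ties at the boundary p-value are resolved by larger overlap, then by
    (query_batch, query_cluster) order.  Input order is preserved; the
    pairs are returned with flags set (new objects, input untouched).
    """
    if not pairs:
        raise ValueError("no matched pairs to select from")
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must be in (0, 1]")
    n_keep = max(1, int(np.floor(omega * len(pairs) + 0.5)))
    order = sorted(
        range(len(pairs)),
        key=lambda i: (
            pairs[i].p_value,
            -pairs[i].overlap,
            pairs[i].query_batch,
            pairs[i].query_cluster,
        ),
    )
    keep = set(order[:n_keep])
    return [
        MatchedPair(
            query_batch=pr.query_batch,
            query_cluster=pr.query_cluster,
            ref_cluster=pr.ref_cluster,
            overlap=pr.overlap,
            table=pr.table,
            p_value=pr.p_value,
            putative=(i in keep),
        )
        for i, pr in enumerate(pairs)
    ]
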