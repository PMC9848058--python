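"""Synthetic multi-batch scRNA-seq generator with planted ground truth.

Cells are drawn directly in log-expression space: each cell's value is
its cell type's mean profile, plus an additive per-gene batch shift
(identical for all cells of a batch), plus Gaussian noise, clamped at
zero.  Type mean profiles differ only at disjoint planted marker-gene
blocks.  This emulates exactly the structure the correction method
assumes — shared types across batches, batch-specific technical shifts in
log space, optional batch-private types — while keeping every planted
quantity (type of each cell, marker genes of each type, the shift of each
batch) available as truth for testing.  Count-level realism (dropout,
overdispersion) is deliberately not modeled; see `docs/methods.md`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["SimulationTruth", "simulate_batches", "dataset3_scenario",
           "default_preset"]

BASELINE = 1.0  # baseline log-expression of every gene


@dataclass
class SimulationTruth:
    """Planted parameters and labels of one simulated dataset."""

    type_means: np.ndarray  # (G, T)
    batch_shifts: np.ndarray  # (G, B+1); reference column is 0
    cell_type_of: dict[str, str]  # cell id -> type label
    batch_of: dict[str, str]  # cell id -> batch label
    marker_genes_of_type: dict[str, list[str]]  # type -> planted marker ids
    seed: int


def _type_counts(props: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells to type proportions."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_batches(
    G: int = 500,
    T: int = 4,
    B: int = 1,
    n_per_batch: Sequence[int] | None = None,
    type_proportions: Sequence[Sequence[float]] | None = None,
    marker_per_type: int = 15,
    marker_effect: float = 2.0,
    batch_effect_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    marker_effect_per_type: Sequence[float] | None = None,
) -> tuple[list[ExpressionMatrix], SimulationTruth]:
    """Simulate a reference batch plus B query batches in log space.

    Parameters
    ----------
    G, T, B : int
        Genes, cell types, and query batches (total batches = B + 1; the
        first generated batch, ``batch0``, is the reference).
    n_per_batch : sequence of B+1 ints
        Cells per batch (default 300 each).
    type_proportions : B+1 rows of T proportions summing to 1
        Per-batch type composition; a zero entry makes a type absent from
        that batch (batch-private-type scenarios).  Default: uniform.
    marker_per_type, marker_effect : int, float
        Each type's mean equals the baseline everywhere except at its own
        disjoint block of `marker_per_type` genes, elevated by
        `marker_effect` (log units).  `marker_effect_per_type` overrides
        the effect per type.
    batch_effect_sd : float
        SD of the per-gene additive shift of each query batch (the
        reference shift is exactly zero).
    noise_sd : float
        SD of the per-cell Gaussian noise.

    Returns the batches (shared gene panel, reference first) and the
    planted `SimulationTruth`.  Identical seeds give bit-identical output.
    """
    if T < 2:
        raise ValueError("need at least 2 cell types")
    if G < T * marker_per_type:
        raise ValueError("gene panel too small for disjoint marker blocks")
    n_batches = B + 1
    if n_per_batch is None:
        n_per_batch = [300] * n_batches
    n_per_batch = list(n_per_batch)
    if len(n_per_batch) != n_batches:
        raise ValueError(f"n_per_batch must list {n_batches} batch sizes")
    if type_proportions is None:
        type_proportions = [[1.0 / T] * T for _ in range(n_batches)]
    props = np.asarray(type_proportions, dtype=float)
    if props.shape != (n_batches, T):
        raise ValueError(f"type_proportions must be {n_batches} x {T}")
    if not np.allclose(props.sum(axis=1), 1.0):
        raise ValueError("each batch's type proportions must sum to 1")
    effects = (
        np.asarray(marker_effect_per_type, dtype=float)
        if marker_effect_per_type is not None
        else np.full(T, float(marker_effect))
    )
    if effects.shape != (T,):
        raise ValueError(f"marker_effect_per_type must have length {T}")

    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(G)]
    type_names = [f"type{t}" for t in range(T)]

    # disjoint marker blocks, then type means
    type_means = np.full((G, T), BASELINE)
    marker_genes_of_type: dict[str, list[str]] = {}
    for t in range(T):
        block = range(t * marker_per_type, (t + 1) * marker_per_type)
        type_means[list(block), t] += effects[t]
        marker_genes_of_type[type_names[t]] = [gene_ids[i] for i in block]

    shifts = np.zeros((G, n_batches))
    if batch_effect_sd > 0:
        shifts[:, 1:] = rng.normal(0.0, batch_effect_sd, size=(G, B))

    batches: list[ExpressionMatrix] = []
    cell_type_of: dict[str, str] = {}
    batch_of: dict[str, str] = {}
    for b in range(n_batches):
        n = n_per_batch[b]
        counts = _type_counts(props[b], n)
        types = np.repeat(np.arange(T), counts)
        means = type_means[:, types] + shifts[:, [b]]
        values = np.maximum(
            means + rng.normal(0.0, noise_sd, size=(G, n)), 0.0
        )
        batch_id = f"batch{b}"
        cell_ids = [f"{batch_id}_cell{j:04d}" for j in range(n)]
        for cid, t in zip(cell_ids, types):
            cell_type_of[cid] = type_names[t]
            batch_of[cid] = batch_id
        batches.append(ExpressionMatrix(values, gene_ids, cell_ids, batch_id))

    truth = SimulationTruth(
        type_means=type_means,
        batch_shifts=shifts,
        cell_type_of=cell_type_of,
        batch_of=batch_of,
        marker_genes_of_type=marker_genes_of_type,
        seed=seed,
    )
    return batches, truth


def default_preset(seed: int = 0) -> tuple[list[ExpressionMatrix], SimulationTruth]:
    """The standard two-batch test world: 500 genes, 4 shared types,
    300 cells per batch, 15 markers/type at effect 2, per-gene batch
    shifts of SD 1, noise SD 0.5."""
    return simulate_batches(
        G=500, T=4, B=1, n_per_batch=[300, 300],
        marker_per_type=15, marker_effect=2.0,
        batch_effect_sd=1.0, noise_sd=0.5, seed=seed,
    )


def dataset3_scenario(seed: int = 0) -> tuple[list[ExpressionMatrix], SimulationTruth]:
    """Two batches with one similar private type each.

    Emulates the structure of a dendritic-cell benchmark: both batches
    contain 96 cells of each of two shared types; in addition, the
    reference batch carries 96 cells of a private type and the query
    batch 96 cells of a different private type.  The two private types
    are given deliberately similar mean profiles (smaller, disjoint
    marker blocks) so that the challenge is to merge the shared types
    across batches while keeping the two similar private types apart.
    Expression values are synthetic; only the design is borrowed.
    """
    # types: 0,1 shared (strong markers); 2 private to reference,
    # 3 private to query (weak markers -> mutually similar profiles)
    props = [
        [96 / 288, 96 / 288, 96 / 288, 0.0],
        [96 / 288, 96 / 288, 0.0, 96 / 288],
    ]
    return simulate_batches(
        G=500, T=4, B=1,
        n_per_batch=[288, 288],
        type_proportions=props,
        marker_per_type=10,
        marker_effect_per_type=[2.0, 2.0, 1.0, 1.0],
        batch_effect_sd=1.0,
        noise_sd=0.5,
        seed=seed,
    )
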