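"""Nearest-neighbor spatial contact analysis.

The neighborhood statistic assigned to each query cell (e.g. each
plasmablast) is the median Euclidean center-to-center distance to its
``k`` nearest cells of a target subset (default ``k = 5``). A query
cell is in "contact" with the target subset when its statistic falls
at or below the contact threshold (default 10 um). Because the
contact fraction can equally be read off the single nearest-neighbor
distance, both versions are always computed and reported.

Significance against cell abundance is assessed with a permutation
null that redraws the target subset (preserving its size) uniformly
from all non-query cells and recomputes the contact fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class SpatialParams:
    k: int = 5
    contact_threshold_um: float = 10.0
    bin_width_um: float = 5.0
    permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.contact_threshold_um <= 0:
            raise ValueError("contact_threshold must be > 0")


@dataclass
class NeighborStats:
    """Per-query-cell statistics plus aggregates.

    ``per_cell`` columns: ``query_id``, ``statistic_um`` (median of
    the k nearest target distances), ``nn1_um`` (single nearest
    neighbor), ``n_targets_used``.
    """

    per_cell: pd.DataFrame
    params: SpatialParams

    def contact_fraction(self, which: str = "median_k") -> float:
        col = {"median_k": "statistic_um", "nn1": "nn1_um"}[which]
        vals = self.per_cell[col].to_numpy()
        if len(vals) == 0:
            raise ValueError("empty statistics")
        return float(np.mean(vals <= self.params.contact_threshold_um))

    def histogram(self, which: str = "median_k") -> tuple[np.ndarray, np.ndarray]:
        """Right-open bins of width ``bin_width_um`` starting at 0."""
        col = {"median_k": "statistic_um", "nn1": "nn1_um"}[which]
        vals = self.per_cell[col].to_numpy()
        hi = self.params.bin_width_um * (
            1 + int(np.max(vals) // self.params.bin_width_um) if len(vals) else 1
        )
        edges = np.arange(0.0, hi + self.params.bin_width_um, self.params.bin_width_um)
        counts, edges = np.histogram(vals, bins=edges)
        return counts, edges

    def to_report(self) -> dict:
        return {
            "n_query": int(len(self.per_cell)),
            "k": self.params.k,
            "contact_threshold_um": self.params.contact_threshold_um,
            "contact_fraction_median_k": self.contact_fraction("median_k"),
            "contact_fraction_nn1": self.contact_fraction("nn1"),
            "median_statistic_um": float(self.per_cell["statistic_um"].median())
            if len(self.per_cell)
            else None,
        }


def neighbor_statistic(
    query_xy: np.ndarray,
    target_xy: np.ndarray,
    params: SpatialParams | None = None,
    query_ids: np.ndarray | None = None,
    target_ids: np.ndarray | None = None,
) -> NeighborStats:
    """Median distance to the k nearest target cells, per query cell.

    Coordinates are in um, one row per cell. When a cell id appears in
    both sets it never pairs with itself. If fewer than ``k`` targets
    are available the median of all available distances is used and
    ``n_targets_used`` records how many.
    """
    params = params or SpatialParams()
    query_xy = np.asarray(query_xy, dtype=np.float64).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=np.float64).reshape(-1, 2)
    if len(target_xy) == 0:
        raise ValueError("target set is empty")
    if query_ids is None:
        query_ids = np.arange(len(query_xy))
    if target_ids is None:
        target_ids = np.full(len(target_xy), -1)
    query_ids = np.asarray(query_ids)
    target_ids = np.asarray(target_ids)

    tree = cKDTree(target_xy)
    kq = min(params.k + 1, len(target_xy))
    _, idx = tree.query(query_xy, k=kq)
    idx = np.atleast_2d(idx)

    stats = np.empty(len(query_xy))
    nn1 = np.empty(len(query_xy))
    n_used = np.empty(len(query_xy), dtype=np.int64)
    for i in range(len(query_xy)):
        keep = idx[i][target_ids[idx[i]] != query_ids[i]]
        # recompute with plain hypot so results match an all-pairs
        # brute-force computation bit for bit
        d = np.hypot(
            target_xy[keep, 0] - query_xy[i, 0],
            target_xy[keep, 1] - query_xy[i, 1],
        )
        d = np.sort(d)[: params.k]
        if len(d) == 0:
            raise ValueError("a query cell has no admissible target")
        stats[i] = float(np.median(d))
        nn1[i] = float(d[0])
        n_used[i] = len(d)
    per_cell = pd.DataFrame(
        {
            "query_id": query_ids,
            "statistic_um": stats,
            "nn1_um": nn1,
            "n_targets_used": n_used,
        }
    )
    return NeighborStats(per_cell=per_cell, params=params)


def contact_fraction(stats: NeighborStats, params: SpatialParams | None = None,
                     which: str = "median_k") -> float:
    """Fraction of query cells whose statistic is at or below the
    contact threshold."""
    if params is not None and params is not stats.params:
        stats = NeighborStats(per_cell=stats.per_cell, params=params)
    return stats.contact_fraction(which)


def abundance_null(
    query_xy: np.ndarray,
    target_xy: np.ndarray,
    pool_xy: np.ndarray,
    params: SpatialParams | None = None,
    which: str = "nn1",
    query_ids: np.ndarray | None = None,
    pool_ids: np.ndarray | None = None,
    target_ids: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Abundance-controlled permutation null for the contact fraction.

    Each of ``params.permutations`` draws reassigns the target label to
    ``len(target_xy)`` cells sampled uniformly without replacement from
    the pool of all non-query cells, preserving target abundance, and
    recomputes the contact fraction. Returns ``(null_fractions, p,
    observed)`` with the empirical ``p = (1 + #{null >= observed}) /
    (B + 1)``.
    """
    params = params or SpatialParams()
    b = params.permutations
    if b < 1:
        raise ValueError("permutations must be >= 1")
    pool_xy = np.asarray(pool_xy, dtype=np.float64).reshape(-1, 2)
    target_xy = np.asarray(target_xy, dtype=np.float64).reshape(-1, 2)
    n_target = len(target_xy)
    if n_target > len(pool_xy):
        raise ValueError("target abundance exceeds the available pool")
    observed = neighbor_statistic(
        query_xy, target_xy, params, query_ids=query_ids, target_ids=target_ids
    ).contact_fraction(which)
    rng = np.random.default_rng(params.seed)
    null = np.empty(b)
    for j in range(b):
        pick = rng.choice(len(pool_xy), size=n_target, replace=False)
        ids = pool_ids[pick] if pool_ids is not None else None
        null[j] = neighbor_statistic(
            query_xy, pool_xy[pick], params, query_ids=query_ids, target_ids=ids
        ).contact_fraction(which)
    p = (1.0 + float(np.sum(null >= observed))) / (b + 1.0)
    return null, p, observed
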