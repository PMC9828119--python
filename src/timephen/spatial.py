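"""Radius-based cell-cell spatial interaction metrics within a core.

"Close contact" between two cells is Euclidean distance <= radius (closed
ball; default radius 20 um, configurable and stamped into every result).
Neighbor search uses uniform spatial grid hashing with cell size equal to
the radius, so only the 3x3 block of grid bins around a query point is
scanned; results are exactly those of the O(n^2) scan.

The headline statistic is the mean number of target-population cells within
the radius of each source-population cell (self excluded when source and
target overlap).  Reflexive queries (e.g. CD8 vs CD8) measure spatial
self-clustering of a population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import POPULATION_PREDICATES

DEFAULT_RADIUS_UM = 20.0


@dataclass(frozen=True)
class NeighborQuery:
    source: str  # key of POPULATION_PREDICATES
    target: str
    radius_um: float = DEFAULT_RADIUS_UM

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")


@dataclass
class InteractionResult:
    core_id: str
    query: NeighborQuery
    n_source: int
    mean_neighbors: float  # NaN when n_source == 0
    counts: np.ndarray  # per-source-cell neighbor counts


class _Grid:
    """Uniform spatial hash: bin side = radius, so neighbors live in 3x3 bins."""

    def __init__(self, x: np.ndarray, y: np.ndarray, radius: float):
        self.x, self.y, self.r = x, y, radius
        self.bins: dict[tuple[int, int], np.ndarray] = {}
        bx = np.floor(x / radius).astype(np.int64)
        by = np.floor(y / radius).astype(np.int64)
        order = np.lexsort((by, bx))
        if len(order):
            keys = np.stack([bx[order], by[order]], axis=1)
            change = np.nonzero((np.diff(keys, axis=0) != 0).any(axis=1))[0] + 1
            for chunk in np.split(order, change):
                self.bins[(int(bx[chunk[0]]), int(by[chunk[0]]))] = chunk

    def count_within(self, qx: np.ndarray, qy: np.ndarray, self_stored: np.ndarray | None = None) -> np.ndarray:
        """Number of stored points within the closed ball of each query point.

        ``self_stored`` marks query points that are themselves stored points
        (reflexive queries); the point itself sits at distance 0, always
        inside the closed ball, so it is subtracted from its own count.
        """
        r2 = self.r * self.r
        out = np.zeros(len(qx), dtype=np.int64)
        qbx = np.floor(qx / self.r).astype(np.int64)
        qby = np.floor(qy / self.r).astype(np.int64)
        # queries sharing a grid bin share the same 3x3 candidate block
        order = np.lexsort((qby, qbx))
        pos = 0
        while pos < len(order):
            end = pos
            bx, by = qbx[order[pos]], qby[order[pos]]
            while end < len(order) and qbx[order[end]] == bx and qby[order[end]] == by:
                end += 1
            group = order[pos:end]
            cand = [
                self.bins[(bx + dx, by + dy)]
                for dx in (-1, 0, 1)
                for dy in (-1, 0, 1)
                if (bx + dx, by + dy) in self.bins
            ]
            if cand:
                idx = np.concatenate(cand)
                d2 = (self.x[idx][None, :] - qx[group][:, None]) ** 2 + (
                    self.y[idx][None, :] - qy[group][:, None]
                ) ** 2
                out[group] = (d2 <= r2).sum(axis=1)
            pos = end
        if self_stored is not None:
            out[self_stored] -= 1
        return out


def neighbor_graph(cells: pd.DataFrame, radius_um: float = DEFAULT_RADIUS_UM) -> list[np.ndarray]:
    """Adjacency lists: for each cell the indices of cells within ``radius_um``.

    Symmetric by construction; a pair at exactly the radius is adjacent.
    """
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    grid = _Grid(x, y, radius_um)
    r2 = radius_um * radius_um
    qbx = np.floor(x / radius_um).astype(np.int64)
    qby = np.floor(y / radius_um).astype(np.int64)
    adj: list[np.ndarray] = []
    for i in range(len(x)):
        found = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                idx = grid.bins.get((qbx[i] + dx, qby[i] + dy))
                if idx is None:
                    continue
                d2 = (x[idx] - x[i]) ** 2 + (y[idx] - y[i]) ** 2
                found.append(idx[(d2 <= r2) & (idx != i)])
        adj.append(np.sort(np.concatenate(found)) if found else np.empty(0, dtype=np.int64))
    return adj


def mean_neighbor_count(cells: pd.DataFrame, query: NeighborQuery, core_id: str = "") -> InteractionResult:
    """Mean number of target cells within radius of each source cell.

    Self is excluded whenever a source cell is also a target cell.  With no
    source cells the mean is missing (NaN); with no targets it is 0.
    """
    src_mask = POPULATION_PREDICATES[query.source](cells).to_numpy()
    tgt_mask = POPULATION_PREDICATES[query.target](cells).to_numpy()
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)

    n_source = int(src_mask.sum())
    if n_source == 0:
        return InteractionResult(core_id, query, 0, float("nan"), np.empty(0, dtype=np.int64))

    tgt_idx = np.nonzero(tgt_mask)[0]
    grid = _Grid(x[tgt_idx], y[tgt_idx], query.radius_um)
    src_idx = np.nonzero(src_mask)[0]
    counts = grid.count_within(x[src_idx], y[src_idx], self_stored=tgt_mask[src_idx])
    return InteractionResult(core_id, query, n_source, float(counts.mean()), counts)


def interaction_matrix(
    cells: pd.DataFrame,
    populations: tuple[str, ...],
    radius_um: float = DEFAULT_RADIUS_UM,
    core_id: str = "",
) -> pd.DataFrame:
    """Pairwise mean-neighbor matrix M[a][b] = mean #b-neighbors per a-cell.

    Not symmetric in general (row normalization differs); the diagonal is a
    self-clustering statistic with self excluded.
    """
    out = pd.DataFrame(index=list(populations), columns=list(populations), dtype=float)
    for a in populations:
        for b in populations:
            res = mean_neighbor_count(cells, NeighborQuery(a, b, radius_um), core_id)
            out.loc[a, b] = res.mean_neighbors
    return out


def cohort_interactions(
    cohort_cells: pd.DataFrame,
    queries: list[NeighborQuery],
) -> pd.DataFrame:
    """Per-core interaction results for a list of queries (long form)."""
    rows = []
    for core_id, group in cohort_cells.groupby("core_id", sort=False):
        g = group.reset_index(drop=True)
        for q in queries:
            res = mean_neighbor_count(g, q, core_id=str(core_id))
            rows.append(
                {
                    "core_id": core_id,
                    "source": q.source,
                    "target": q.target,
                    "radius_um": q.radius_um,
                    "n_source": res.n_source,
                    "mean_neighbors": res.mean_neighbors,
                    "sd_neighbors": float(res.counts.std(ddof=1)) if res.n_source > 1 else float("nan"),
                }
            )
    return pd.DataFrame(rows)
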