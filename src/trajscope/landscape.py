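"""Free-energy landscapes by Boltzmann inversion of a 2-D histogram.

For two collective-variable series (by default Rg and RMSD) binned on an
(nx, ny) grid, the free energy of occupied bin i is

    G_i = -k_B T ln(N_i / N_max)        [kcal/mol]

with k_B = 0.0019872041 kcal/(mol K).  The most populated bin sits at
G = 0 exactly.  Empty bins have no defined free energy; they are flagged
and assigned an artificial barrier of (max occupied G) + k_B T so the
surface stays finite for plotting and basin growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .geometry import SeriesResult

KB_KCAL = 0.0019872041  # kcal/(mol K)


@dataclass
class FELGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray        # (nx, ny) integers
    G: np.ndarray             # kcal/mol
    empty_mask: np.ndarray    # True where no frames fell
    temperature: float        # K
    kB: float = KB_KCAL
    x_label: str = "x"
    y_label: str = "y"

    @property
    def barrier(self) -> float:
        """Artificial free energy assigned to empty bins."""
        occ = self.G[~self.empty_mask]
        return float(occ.max() + self.kB * self.temperature)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]))


@dataclass
class Basin:
    minimum_bin: tuple[int, int]
    member_bins: list[tuple[int, int]]
    depth: float               # barrier - G(minimum), kcal/mol
    population_fraction: float
    g_min: float = 0.0


def _padded_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        lo, hi = lo - 0.5, hi + 0.5
    width = (hi - lo) / n_bins
    return np.linspace(lo - width / 2, hi + width / 2, n_bins + 1)


def compute_fel(x: SeriesResult, y: SeriesResult,
                n_bins: tuple[int, int] = (50, 50),
                temperature: float = 300.0) -> FELGrid:
    """Boltzmann-inverted 2-D free-energy surface over (x, y) bins.

    The grid spans the observed data range padded by half a bin on each
    side, so extreme frames never sit on an edge.
    """
    xv, yv = x.values, y.values
    if len(xv) != len(yv):
        raise ValueError("series lengths differ")
    if len(xv) < 1:
        raise ValueError("empty series")
    nx, ny = n_bins
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 bins per axis")
    x_edges = _padded_edges(xv, nx)
    y_edges = _padded_edges(yv, ny)
    counts, _, _ = np.histogram2d(xv, yv, bins=(x_edges, y_edges))
    counts = counts.astype(int)
    empty = counts == 0
    n_max = counts.max()
    G = np.zeros_like(counts, dtype=float)
    occ = ~empty
    G[occ] = -KB_KCAL * temperature * np.log(counts[occ] / n_max)
    barrier = G[occ].max() + KB_KCAL * temperature
    G[empty] = barrier
    return FELGrid(x_edges=x_edges, y_edges=y_edges, counts=counts, G=G,
                   empty_mask=empty, temperature=temperature,
                   x_label=x.metric, y_label=y.metric)


_NEIGHBOURS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
               if (di, dj) != (0, 0)]


def locate_minima(grid: FELGrid) -> list[Basin]:
    """Local minima of the occupied surface and their steepest-descent basins.

    A bin is a local minimum if no occupied 8-neighbour has strictly lower
    G (ties broken toward smaller (i, j), so a flat plateau yields one
    basin).  Every occupied bin is assigned to a basin by following the
    steepest descending neighbour; basins are returned ordered by ascending
    minimum G, then ascending bin index.
    """
    occ = ~grid.empty_mask
    if not occ.any():
        raise ValueError("grid has no occupied bins")
    nx, ny = grid.G.shape

    def descend_target(i: int, j: int) -> tuple[int, int]:
        best = (grid.G[i, j], (i, j))
        for di, dj in _NEIGHBOURS:
            a, b = i + di, j + dj
            if 0 <= a < nx and 0 <= b < ny and occ[a, b]:
                cand = (grid.G[a, b], (a, b))
                if cand < best:
                    best = cand
        return best[1]

    assignment: dict[tuple[int, int], tuple[int, int]] = {}

    def root(cell: tuple[int, int]) -> tuple[int, int]:
        path = []
        while cell not in assignment:
            nxt = descend_target(*cell)
            if nxt == cell:
                assignment[cell] = cell
                break
            path.append(cell)
            cell = nxt
        r = assignment[cell] if cell in assignment else cell
        # path-compress via the recorded root
        while r != assignment.get(r, r):
            r = assignment[r]
        for p in path:
            assignment[p] = r
        return r

    cells = [(i, j) for i in range(nx) for j in range(ny) if occ[i, j]]
    members: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for cell in cells:
        r = root(cell)
        members.setdefault(r, []).append(cell)

    total = grid.counts.sum()
    basins = []
    for r, cells_r in members.items():
        pop = sum(grid.counts[c] for c in cells_r) / total
        basins.append(Basin(minimum_bin=r, member_bins=sorted(cells_r),
                            depth=grid.barrier - float(grid.G[r]),
                            population_fraction=float(pop),
                            g_min=float(grid.G[r])))
    basins.sort(key=lambda b: (b.g_min, b.minimum_bin))
    return basins


def representative_frame(traj: Trajectory, x: SeriesResult, y: SeriesResult,
                         grid: FELGrid, basin: Basin) -> int:
    """Frame index best representing a basin's free-energy minimum.

    Among frames landing in the basin's minimum bin, returns the one
    closest (Euclidean, each axis scaled by its bin width) to the bin
    centre; ties go to the lowest frame index.
    """
    if len(x.values) != traj.n_frames or len(y.values) != traj.n_frames:
        raise ValueError("series do not align with trajectory frames")
    i, j = basin.minimum_bin
    xc, yc = grid.bin_centers()
    wx = grid.x_edges[1] - grid.x_edges[0]
    wy = grid.y_edges[1] - grid.y_edges[0]
    ix = np.clip(np.digitize(x.values, grid.x_edges) - 1, 0, len(xc) - 1)
    iy = np.clip(np.digitize(y.values, grid.y_edges) - 1, 0, len(yc) - 1)
    in_bin = np.nonzero((ix == i) & (iy == j))[0]
    if len(in_bin) == 0:
        raise ValueError("no frames fall in the basin's minimum bin")
    d2 = (((x.values[in_bin] - xc[i]) / wx) ** 2
          + ((y.values[in_bin] - yc[j]) / wy) ** 2)
    return int(in_bin[np.argmin(d2)])
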