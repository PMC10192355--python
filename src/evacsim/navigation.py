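"""Cost-raster navigation fields.

A land-use raster is mapped to a traversal-cost raster (road 1,
building 4000, water 8000, other 2000), and the navigation field is
the minimum cumulative cost from the destination set over the
8-connected grid graph.  The edge weight between adjacent cells is the
step length (``res`` straight, ``res * sqrt(2)`` diagonal) times the
arithmetic mean of the two endpoint cell costs — the semantics of
classical raster cost-distance tools.  Each cell's desired direction
is the unit vector toward its steepest-descent neighbour, so following
directions greedily always reaches a destination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from evacsim.urban import BUILDING, OTHER, ROAD, WATER, UrbanModel

#: default traversal cost per land-use category (dimensionless multiplier per metre)
DEFAULT_COSTS = {ROAD: 1.0, BUILDING: 4000.0, WATER: 8000.0, OTHER: 2000.0}

# 8-neighbourhood offsets as (drow, dcol)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CostMap:
    """Per-cell traversal cost (strictly positive), plus the cell size."""

    costs: np.ndarray  # (ny, nx) float
    resolution: float = 1.0

    def __post_init__(self) -> None:
        if self.costs.size == 0:
            raise ValueError("empty cost raster")
        if not (np.asarray(self.costs) > 0).all():
            raise ValueError("traversal costs must be strictly positive")


def build_cost_map(
    landuse: np.ndarray,
    resolution: float = 1.0,
    cost_table: dict[int, float] | None = None,
) -> CostMap:
    """Map a land-use category raster to a traversal-cost raster.

    Raises ``ValueError`` on an empty raster or a category code absent
    from the (overridable) cost table.
    """
    landuse = np.asarray(landuse)
    if landuse.size == 0:
        raise ValueError("empty land-use raster")
    table = dict(DEFAULT_COSTS if cost_table is None else cost_table)
    cats = np.unique(landuse)
    unknown = [int(c) for c in cats if int(c) not in table]
    if unknown:
        raise ValueError(f"unknown land-use categories {unknown} (cost table has {sorted(table)})")
    lut = np.zeros(int(max(table)) + 1)
    for k, v in table.items():
        lut[k] = v
    return CostMap(costs=lut[landuse].astype(float), resolution=resolution)


@dataclass
class NavigationField:
    """Minimum cumulative cost from the destination set, and descent directions.

    ``cumcost`` is 0 at destination cells and finite on every cell
    reachable from a destination.  ``direction`` holds per-cell unit
    vectors (x, y) toward the steepest-descent neighbour; it is the
    zero vector at destination cells and on unreachable cells.
    """

    cumcost: np.ndarray  # (ny, nx) float
    direction: np.ndarray  # (ny, nx, 2) float32 unit vectors
    resolution: float
    destination_cells: np.ndarray  # (k, 2) int (row, col)

    def directions_at(self, points: np.ndarray) -> np.ndarray:
        """Desired-direction unit vectors for metric points (n, 2)."""
        row, col = self._cells(points)
        return np.asarray(self.direction[row, col], dtype=float)

    def cost_at(self, points: np.ndarray) -> np.ndarray:
        row, col = self._cells(points)
        return self.cumcost[row, col]

    def _cells(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ny, nx = self.cumcost.shape
        ex, ey = nx * self.resolution, ny * self.resolution
        if np.any((pts[:, 0] < 0) | (pts[:, 0] >= ex) | (pts[:, 1] < 0) | (pts[:, 1] >= ey)):
            raise ValueError("position outside domain")
        col = np.minimum((pts[:, 0] / self.resolution).astype(np.intp), nx - 1)
        row = np.minimum((pts[:, 1] / self.resolution).astype(np.intp), ny - 1)
        return row, col


def _grid_graph(costs: np.ndarray, resolution: float, connectivity: int) -> coo_matrix:
    ny, nx = costs.shape
    n = ny * nx
    idx = np.arange(n).reshape(ny, nx)
    rows, cols, data = [], [], []
    offsets = [(0, 1), (1, 0)] if connectivity == 4 else [(0, 1), (1, 0), (1, 1), (1, -1)]
    for di, dj in offsets:
        step = resolution * np.hypot(di, dj)
        i0, i1 = max(0, -di), min(ny, ny - di)
        j0, j1 = max(0, -dj), min(nx, nx - dj)
        a = idx[i0:i1, j0:j1]
        b = idx[i0 + di : i1 + di, j0 + dj : j1 + dj]
        w = step * 0.5 * (costs[i0:i1, j0:j1] + costs[i0 + di : i1 + di, j0 + dj : j1 + dj])
        rows.append(a.ravel())
        cols.append(b.ravel())
        data.append(w.ravel())
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )


def compute_navigation_field(
    cost: CostMap,
    destinations: np.ndarray,
    connectivity: int = 8,
) -> NavigationField:
    """Multi-source shortest path over the cost raster's grid graph.

    Parameters
    ----------
    cost : CostMap
    destinations : array (k, 2)
        Destination points in metres; each must fall inside the raster.
    connectivity : {4, 8}
        Grid neighbourhood (8 by default, with sqrt(2) diagonal steps).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    costs = np.asarray(cost.costs, dtype=float)
    ny, nx = costs.shape
    res = cost.resolution
    dests = np.atleast_2d(np.asarray(destinations, dtype=float))
    if dests.size == 0:
        raise ValueError("need at least one destination")
    col = (dests[:, 0] / res).astype(np.intp)
    row = (dests[:, 1] / res).astype(np.intp)
    if np.any((col < 0) | (col >= nx) | (row < 0) | (row >= ny)):
        raise ValueError("destination outside raster")
    dest_flat = np.unique(row * nx + col)

    graph = _grid_graph(costs, res, connectivity).tocsr()
    dist = dijkstra(graph, directed=False, indices=dest_flat, min_only=True)
    field = dist.reshape(ny, nx)

    direction = _descent_directions(field, connectivity)
    dest_cells = np.column_stack([dest_flat // nx, dest_flat % nx])
    direction[dest_cells[:, 0], dest_cells[:, 1]] = 0.0
    return NavigationField(
        cumcost=field, direction=direction, resolution=res, destination_cells=dest_cells
    )


def _descent_directions(field: np.ndarray, connectivity: int) -> np.ndarray:
    """Unit vector per cell toward the neighbour of minimum cumulative cost."""
    ny, nx = field.shape
    offsets = _OFFSETS if connectivity == 8 else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    stacked = np.full((len(offsets), ny, nx), np.inf)
    for k, (di, dj) in enumerate(offsets):
        i0, i1 = max(0, -di), min(ny, ny - di)
        j0, j1 = max(0, -dj), min(nx, nx - dj)
        stacked[k, i0:i1, j0:j1] = field[i0 + di : i1 + di, j0 + dj : j1 + dj]
    best = np.argmin(stacked, axis=0)
    best_val = np.take_along_axis(stacked, best[None], axis=0)[0]

    vecs = np.array([(dj, di) for di, dj in offsets], dtype=float)
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    direction = vecs[best].astype(np.float32)
    # no descent at local minima (destinations) or on unreachable cells
    flat = ~(best_val < field)
    direction[flat] = 0.0
    return direction


def desired_direction(field: NavigationField, position: np.ndarray) -> np.ndarray:
    """Unit desired-direction vector at a single metric position.

    Zero at destination cells; raises ``ValueError`` outside the domain.
    """
    return field.directions_at(np.asarray(position, dtype=float).reshape(1, 2))[0]


def navigation_field_for(urban: UrbanModel, connectivity: int = 8) -> NavigationField:
    """Convenience: cost map plus navigation field for an urban model."""
    cost = build_cost_map(urban.landuse, resolution=urban.resolution)
    return compute_navigation_field(cost, urban.destinations, connectivity=connectivity)
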