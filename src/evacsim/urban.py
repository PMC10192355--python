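"""Synthetic urban models: grid-like and root-like street structures.

Two generator styles capture the structural contrast between a dense
coastal-plain city (orthogonal street lattice, contiguous building
blocks, few inland exits) and a ria-coast valley town (a branching,
funnel-shaped road skeleton with wider roads, sparser buildings and
many uphill exits).  Both produce the same :class:`UrbanModel`: a
land-use raster, building polygons, destination points and road
centrelines in a local metric frame with the origin at the south-west
corner.

Land-use category codes (raster values):

====  =========
code  category
====  =========
0     other
1     road
2     building
3     water
====  =========
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box
from shapely import affinity

OTHER, ROAD, BUILDING, WATER = 0, 1, 2, 3
CATEGORY_NAMES = {OTHER: "other", ROAD: "road", BUILDING: "building", WATER: "water"}

#: style-dependent defaults: (road_width m, building_coverage, n_destinations,
#: inundation_depth_fraction)
_STYLE_DEFAULTS = {
    "grid": (6.0, 0.5, 2, 0.2),
    "root": (12.0, 0.4, 6, 0.5),
}

_COAST_ANGLES = {"S": 0.0, "E": 90.0, "N": 180.0, "W": -90.0}
_COAST_ROT90 = {"S": 0, "E": 3, "N": 2, "W": 1}


@dataclass
class CityParams:
    """Parameters of a synthetic city.

    Parameters
    ----------
    style : {"grid", "root"}
        Grid: orthogonal street lattice, coast along one edge, few
        destinations on the opposite (inland) edge.  Root: branching
        road skeleton funnelling from a coastal valley mouth toward
        many uphill destinations.
    extent : float
        Side length of the square domain in metres.
    resolution : float
        Raster cell size in metres (1 m resolves narrow streets).
    coast_side : {"S", "N", "E", "W"}
        Which boundary edge represents the sea.
    road_width : float, optional
        Street width in metres.  Defaults depend on style; the root
        style must remain strictly wider than the default grid style.
    street_spacing : float
        Grid style only: distance between parallel street centrelines.
    branch_count : int
        Root style only: number of primary branches off the trunk.
    branch_angle : float
        Root style only: angular spread of primary branches (degrees).
    building_coverage : float, optional
        Fraction of candidate building lots that are realised.
        Defaults depend on style; root must stay below the grid default.
    n_destinations : int, optional
        Number of evacuation destination points (grid default 2,
        root default 6 at desk scale).
    inundation_depth_fraction : float, optional
        Fraction of the domain adjacent to the coast treated as the
        inundation zone (used for agent placement and destination
        siting only; no hydrodynamics).  Grid default 0.35 — a plain
        city concentrates its at-risk blocks in a low-lying coastal
        band; root default 0.5.
    seed : int
        Seed for the stochastic parts of the generator (building lots).
    """

    style: str
    extent: float = 500.0
    resolution: float = 1.0
    coast_side: str = "S"
    road_width: float | None = None
    street_spacing: float = 50.0
    branch_count: int = 3
    branch_angle: float = 35.0
    building_coverage: float | None = None
    n_destinations: int | None = None
    inundation_depth_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in _STYLE_DEFAULTS:
            raise ValueError(f"unknown style {self.style!r}")
        if self.coast_side not in _COAST_ANGLES:
            raise ValueError(f"coast_side must be one of {sorted(_COAST_ANGLES)}")
        w, cov, nd, frac = _STYLE_DEFAULTS[self.style]
        if self.road_width is None:
            self.road_width = w
        if self.building_coverage is None:
            self.building_coverage = cov
        if self.n_destinations is None:
            self.n_destinations = nd
        if self.inundation_depth_fraction is None:
            self.inundation_depth_fraction = frac
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.extent / self.resolution < 10:
            raise ValueError("degenerate extent: domain must span at least 10 cells")
        if not 0.0 <= self.building_coverage <= 1.0:
            raise ValueError("building_coverage must be in [0, 1]")
        if self.n_destinations < 1:
            raise ValueError("need at least one destination")
        if self.style == "root":
            grid_w, grid_cov, _, _ = _STYLE_DEFAULTS["grid"]
            if self.road_width <= grid_w:
                raise ValueError(
                    "root style requires roads strictly wider than the grid default"
                )
            if self.building_coverage >= grid_cov:
                raise ValueError(
                    "root style requires building coverage below the grid default"
                )


@dataclass
class UrbanModel:
    """A synthetic (or loaded) urban model in local metric coordinates.

    The raster is row-major with cell ``(0, 0)`` at the origin
    (south-west corner); cells are half-open ``[x, x + res)``.
    """

    bounds: tuple[float, float, float, float]
    resolution: float
    landuse: np.ndarray  # (ny, nx) uint8, category codes
    buildings: list[Polygon]
    destinations: np.ndarray  # (k, 2) metres
    road_lines: list[LineString]
    coast_side: str = "S"
    style: str | None = None
    params: CityParams | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.landuse.shape

    @property
    def extent(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bounds
        return (x1 - x0, y1 - y0)

    def cell_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map metric points (n, 2) to raster (row, col) indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x0, y0, x1, y1 = self.bounds
        if np.any((pts[:, 0] < x0) | (pts[:, 0] >= x1) | (pts[:, 1] < y0) | (pts[:, 1] >= y1)):
            raise ValueError("point outside domain bounds")
        col = ((pts[:, 0] - x0) / self.resolution).astype(np.intp)
        row = ((pts[:, 1] - y0) / self.resolution).astype(np.intp)
        ny, nx = self.landuse.shape
        return np.minimum(row, ny - 1), np.minimum(col, nx - 1)

    def category_at(self, points: np.ndarray) -> np.ndarray:
        row, col = self.cell_index(points)
        return self.landuse[row, col]

    def inundation_polygon(self) -> Polygon:
        """Band of the domain adjacent to the coast edge.

        Depth is ``inundation_depth_fraction`` of the domain extent
        (0.5 when the model carries no generator parameters).
        """
        frac = self.params.inundation_depth_fraction if self.params else 0.5
        x0, y0, x1, y1 = self.bounds
        d = frac * ((y1 - y0) if self.coast_side in "SN" else (x1 - x0))
        if self.coast_side == "S":
            return box(x0, y0, x1, y0 + d)
        if self.coast_side == "N":
            return box(x0, y1 - d, x1, y1)
        if self.coast_side == "W":
            return box(x0, y0, x0 + d, y1)
        return box(x1 - d, y0, x1, y1)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not np.isin(self.landuse, [OTHER, ROAD, BUILDING, WATER]).all():
            raise ValueError("landuse raster contains unknown category codes")
        if len(self.destinations):
            cats = self.category_at(self.destinations)
            if not (cats == ROAD).all():
                raise ValueError("every destination must lie on a road cell")


def _cell_centres(n: int, res: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * res


def rasterise(
    road_lines: list[LineString],
    buildings: list[Polygon],
    extent: float,
    resolution: float,
    road_width: float,
) -> np.ndarray:
    """Rasterise vector roads and buildings onto a land-use grid.

    Roads are centrelines buffered to ``road_width`` (flat caps so a
    street ending on the boundary does not bulge past it); buildings
    are filled where the cell centre falls inside a polygon.  Roads
    take precedence over buildings on overlap.  Deterministic and
    idempotent: same inputs, same grid.
    """
    n = int(round(extent / resolution))
    landuse = np.full((n, n), OTHER, dtype=np.uint8)
    xc = _cell_centres(n, resolution)
    # buildings first so that roads win on overlap
    for poly in buildings:
        bx0, by0, bx1, by1 = poly.bounds
        c0 = max(0, int(bx0 / resolution))
        c1 = min(n, int(math.ceil(bx1 / resolution)))
        r0 = max(0, int(by0 / resolution))
        r1 = min(n, int(math.ceil(by1 / resolution)))
        if c1 <= c0 or r1 <= r0:
            continue
        gx, gy = np.meshgrid(xc[c0:c1], xc[r0:r1])
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gy.shape)
        landuse[r0:r1, c0:c1][inside] = BUILDING
    if road_lines:
        road_poly = shapely.unary_union(
            [ln.buffer(road_width / 2.0, cap_style="flat") for ln in road_lines]
        )
        shapely.prepare(road_poly)
        gx, gy = np.meshgrid(xc, xc)
        on_road = shapely.intersects_xy(road_poly, gx.ravel(), gy.ravel()).reshape((n, n))
        landuse[on_road] = ROAD
    return landuse


def _grid_skeleton(p: CityParams) -> tuple[list[LineString], list[Polygon], np.ndarray]:
    """Streets, buildings and destinations for the grid style (coast-south frame)."""
    rng = np.random.default_rng(p.seed)
    E, w = p.extent, p.road_width
    n_streets = int(E / p.street_spacing) + 1
    xs = np.array([k * p.street_spacing for k in range(n_streets)])
    xs = xs[xs <= E + 1e-9]

    roads = [LineString([(x, 0.0), (x, E)]) for x in xs]
    roads += [LineString([(0.0, y), (E, y)]) for y in xs]

    # buildings: subdivide each inter-street block into lots and keep a fraction
    buildings: list[Polygon] = []
    margin = 1.5  # clearance between lot and street edge, m
    lot_target = 12.0  # nominal lot pitch, m
    edges = xs
    for bx0, bx1 in zip(edges[:-1], edges[1:]):
        for by0, by1 in zip(edges[:-1], edges[1:]):
            ix0, ix1 = bx0 + w / 2 + margin, bx1 - w / 2 - margin
            iy0, iy1 = by0 + w / 2 + margin, by1 - w / 2 - margin
            if ix1 - ix0 < 4 or iy1 - iy0 < 4:
                continue
            nlx = max(1, int(round((ix1 - ix0) / lot_target)))
            nly = max(1, int(round((iy1 - iy0) / lot_target)))
            lx = (ix1 - ix0) / nlx
            ly = (iy1 - iy0) / nly
            for i in range(nlx):
                for j in range(nly):
                    if rng.random() >= p.building_coverage:
                        continue
                    x0 = ix0 + i * lx + 1.0
                    y0 = iy0 + j * ly + 1.0
                    x1 = ix0 + (i + 1) * lx - 1.0
                    y1 = iy0 + (j + 1) * ly - 1.0
                    if x1 - x0 > 1 and y1 - y0 > 1:
                        buildings.append(box(x0, y0, x1, y1))

    # destinations: on the inland (north) edge, centres of evenly chosen
    # vertical streets that run away from the coast
    interior = xs[(xs > 0) & (xs < E)]
    cand = interior if len(interior) >= p.n_destinations else xs
    picks = np.unique(
        np.round(np.linspace(0, len(cand) - 1, p.n_destinations)).astype(int)
    )
    dest_x = cand[picks]
    dests = np.column_stack([dest_x, np.full(len(dest_x), E - 1.5 * p.resolution)])
    return roads, buildings, dests


def _root_skeleton(p: CityParams) -> tuple[list[LineString], list[Polygon], np.ndarray]:
    """Trunk-and-branch skeleton for the root style (coast-south frame).

    The trunk starts at the coastal valley mouth; primary branches
    split uphill within ``branch_angle`` of vertical and fan out into
    twigs whose tips carry the destinations on the inland edge.
    """
    rng = np.random.default_rng(p.seed)
    E = p.extent
    mouth = (E / 2.0, 0.0)
    j0 = (E / 2.0, 0.35 * E)
    tips = [((i + 0.5) / p.n_destinations * E, E) for i in range(p.n_destinations)]

    groups = np.array_split(np.arange(p.n_destinations), p.branch_count)
    mains = [LineString([mouth, j0])]
    max_dx = 0.30 * E * math.tan(math.radians(p.branch_angle))
    for g in groups:
        if len(g) == 0:
            continue
        gx = float(np.mean([tips[i][0] for i in g]))
        jx = j0[0] + np.clip(gx - j0[0], -max_dx, max_dx)
        jk = (jx, 0.65 * E)
        mains.append(LineString([j0, jk]))
        for i in g:
            mains.append(LineString([jk, tips[i]]))

    # short dead-end lanes branching off the mains: valley settlements
    # string their houses along such lanes, which funnel people onto the
    # through roads (flow gathering) while keeping the structure sparse
    stub_spacing = 0.10 * E
    stub_len = 0.15 * E
    stubs: list[LineString] = []
    domain = box(0, 0, E, E)
    for ln in mains:
        (x0, y0), (x1, y1) = ln.coords
        seg = np.array([x1 - x0, y1 - y0])
        length = float(np.hypot(*seg))
        u = seg / length
        nvec = np.array([-u[1], u[0]])
        s = stub_spacing * 0.7
        while s < length - 0.3 * stub_spacing:
            base = np.array([x0, y0]) + s * u
            for side in (1.0, -1.0):  # paired lanes: hamlets join the main together
                end = base + side * stub_len * nvec
                lane = LineString([tuple(base), tuple(end)]).intersection(domain)
                if lane.length > 0.5 * stub_len:
                    stubs.append(lane)
            s += stub_spacing
    roads = mains + stubs

    # buildings: hamlets of small lots at the lane ends, plus sparse lots
    # strung along the through roads
    buildings: list[Polygon] = []
    lot = 9.0
    gap = 3.0
    off = p.road_width / 2.0 + gap + lot / 2.0
    for ln in roads:
        coords = list(ln.coords)
        (x0, y0), (x1, y1) = coords[0], coords[-1]
        seg = np.array([x1 - x0, y1 - y0])
        length = float(np.hypot(*seg))
        is_stub = ln in stubs
        pitch = 12.0 if is_stub else 40.0
        if length < pitch:
            continue
        u = seg / length
        nvec = np.array([-u[1], u[0]])
        n_lots = int(length / pitch)
        s_min = 0.55 * length if is_stub else 0.0
        for k in range(n_lots):
            s = (k + 0.5) * pitch
            if s < s_min:
                continue
            centre = np.array([x0, y0]) + s * u
            for side in (-1.0, 1.0):
                if rng.random() >= p.building_coverage:
                    continue
                c = centre + side * off * nvec
                half = lot / 2.0
                corners = [
                    c + half * (u + nvec),
                    c + half * (u - nvec),
                    c - half * (u + nvec),
                    c - half * (u - nvec),
                ]
                poly = Polygon([tuple(pt) for pt in corners])
                if poly.within(domain):
                    buildings.append(poly)

    dests = np.array([(x, E - 1.5 * p.resolution) for x, _ in tips])
    return roads, buildings, dests


def _transform_to_coast_side(
    roads: list[LineString],
    buildings: list[Polygon],
    dests: np.ndarray,
    landuse: np.ndarray,
    p: CityParams,
) -> tuple[list[LineString], list[Polygon], np.ndarray, np.ndarray]:
    side = p.coast_side
    if side == "S":
        return roads, buildings, dests, landuse
    angle = _COAST_ANGLES[side]
    centre = (p.extent / 2.0, p.extent / 2.0)
    roads = [affinity.rotate(ln, angle, origin=centre) for ln in roads]
    buildings = [affinity.rotate(pg, angle, origin=centre) for pg in buildings]
    th = math.radians(angle)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    dests = (dests - centre) @ rot.T + centre
    landuse = np.rot90(landuse, _COAST_ROT90[side]).copy()
    return roads, buildings, dests, landuse


def generate_city(params: CityParams) -> UrbanModel:
    """Generate a synthetic city.

    Deterministic given ``params.seed``.  The grid style produces an
    orthogonal street lattice with the coast on ``coast_side`` and
    destinations on the opposite edge; the root style produces a
    connected tree of roads whose branches converge from many uphill
    destination-bearing tips toward a single coastal valley mouth.
    """
    if params.style == "grid":
        roads, buildings, dests = _grid_skeleton(params)
    else:
        roads, buildings, dests = _root_skeleton(params)
    if roads and buildings:
        # drop lots clipped by a road: agents must never stand on road cells
        road_poly = shapely.unary_union(
            [ln.buffer(params.road_width / 2.0, cap_style="flat") for ln in roads]
        )
        shapely.prepare(road_poly)
        buildings = [b for b in buildings if not b.intersects(road_poly)]
    landuse = rasterise(roads, buildings, params.extent, params.resolution, params.road_width)
    roads, buildings, dests, landuse = _transform_to_coast_side(
        roads, buildings, dests, landuse, params
    )
    model = UrbanModel(
        bounds=(0.0, 0.0, params.extent, params.extent),
        resolution=params.resolution,
        landuse=landuse,
        buildings=buildings,
        destinations=np.asarray(dests, dtype=float),
        road_lines=roads,
        coast_side=params.coast_side,
        style=params.style,
        params=replace(params),
    )
    model.validate()
    return model


def place_agents(
    urban: UrbanModel,
    n: int,
    restrict_to_inundation: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` agent start positions uniformly inside buildings.

    Buildings are chosen with probability proportional to their area;
    points are rejection-sampled inside the chosen polygon.  With
    ``restrict_to_inundation`` only buildings intersecting the coastal
    inundation zone are eligible (used for the grid-style city, whose
    at-risk population lives in the low-lying band near the coast).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    buildings = urban.buildings
    if restrict_to_inundation:
        zone = urban.inundation_polygon()
        buildings = [b for b in buildings if b.intersects(zone)]
    if not buildings:
        raise ValueError("no eligible buildings to place agents in")
    rng = np.random.default_rng(seed)
    areas = np.array([b.area for b in buildings])
    probs = areas / areas.sum()
    idx = rng.choice(len(buildings), size=n, p=probs)
    pts = np.empty((n, 2))
    for k, bi in enumerate(idx):
        b = buildings[bi]
        x0, y0, x1, y1 = b.bounds
        while True:
            x = rng.uniform(x0, x1)
            y = rng.uniform(y0, y1)
            if shapely.contains_xy(b, x, y):
                pts[k] = (x, y)
                break
    return pts


def sample_initial_attitudes(n: int, seed: int = 0) -> np.ndarray:
    """i.i.d. Uniform(-1, 1) initial evacuation attitudes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).uniform(-1.0, 1.0, size=n)


def assign_leaders(n_agents: int, n_leaders: int, seed: int = 0) -> np.ndarray:
    """Sample leading-evacuee indices without replacement.

    Returns exactly ``n_leaders`` distinct agent indices (sorted).
    """
    if not 0 <= n_leaders <= n_agents:
        raise ValueError("need 0 <= n_leaders <= n_agents")
    if n_leaders == 0:
        return np.empty(0, dtype=np.intp)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_agents, size=n_leaders, replace=False)).astype(np.intp)
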