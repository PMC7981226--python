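"""Geographic separation between populations.

Populations are summarised by the arithmetic centroid of their members'
WGS84 coordinates. Two separation measures are produced for every pair:

* straight-line distance — great-circle (haversine) metres;
* weighted least-cost-path (LCP) distance — the minimal-cost route across a
  habitat-resistance raster (resistance = 1 - suitability), with the path's
  geometric length multiplied by its mean per-cell resistance.

Under the edge-cost convention used here (mean of the two cell resistances
times the centre-to-centre distance) the weighted distance equals the
accumulated Dijkstra cost, so both readings of "length x resistance" agree;
both numbers are reported regardless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEGREE = EARTH_RADIUS_M * math.pi / 180.0

# 8-connected neighbourhood: (row offset, col offset)
_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class UnreachableError(RuntimeError):
    """No path exists between the requested cells."""


class SnapError(ValueError):
    """A coordinate could not be snapped to a valid raster cell."""


# ---------------------------------------------------------------------------
# points
# ---------------------------------------------------------------------------

def centroid(points) -> tuple[float, float]:
    """Arithmetic mean (lon, lat) of a sequence of (lon, lat) points."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("centroid of an empty point list")
    pts = pts.reshape(-1, 2)
    return float(pts[:, 0].mean()), float(pts[:, 1].mean())


def straight_line_distance(a, b) -> float:
    """Great-circle distance in metres between two (lon, lat) points."""
    lon1, lat1 = a
    lon2, lat2 = b
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dlat = p2 - p1
    dlon = math.radians(lon2 - lon1)
    h = math.sin(dlat / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class PopulationGeo:
    """A named population with member coordinates (lon, lat, WGS84 degrees)."""

    name: str
    members: list = field(default_factory=list)

    @property
    def centroid(self) -> tuple[float, float]:
        return centroid(self.members)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

@dataclass
class ResistanceRaster:
    """Single-band gridded landscape resistance in [0, 1].

    ``values`` is (nrows, ncols) with row 0 the *northern* edge, as in the
    ESRI ASCII grid convention. ``origin`` is the lower-left corner
    (x, y) and ``cellsize`` the cell edge, both in the units named by
    ``crs``: ``"geographic"`` (degrees; east-west metres are corrected by
    cos(latitude) per row) or ``"projected_m"`` (metres).
    """

    values: np.ndarray
    origin: tuple[float, float]
    cellsize: float
    crs: str = "geographic"
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        valid = self.mask
        vals = self.values[valid]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("resistance values must lie in [0, 1]")

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds data."""
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    # -- coordinate transforms ---------------------------------------------
    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell centre; row 0 is the top (northern) row."""
        nrows = self.values.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cellsize
        y = self.origin[1] + (nrows - row - 0.5) * self.cellsize
        return x, y

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        nrows, ncols = self.values.shape
        col = int(math.floor((x - self.origin[0]) / self.cellsize))
        row = int(nrows - 1 - math.floor((y - self.origin[1]) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise SnapError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def cell_sizes_m(self, row: int) -> tuple[float, float]:
        """(dx, dy) metres spanned by one cell in the given row."""
        if self.crs == "projected_m":
            return self.cellsize, self.cellsize
        _, lat = self.cell_center(row, 0)
        dy = self.cellsize * M_PER_DEGREE
        dx = dy * math.cos(math.radians(lat))
        return dx, dy


def invert_suitability(raster: ResistanceRaster) -> ResistanceRaster:
    """resistance = 1 - suitability; nodata cells preserved."""
    vals = raster.values.copy()
    m = raster.mask
    if m.any() and (vals[m].min() < 0 or vals[m].max() > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    vals[m] = 1.0 - vals[m]
    return ResistanceRaster(vals, raster.origin, raster.cellsize, raster.crs, raster.nodata)


def read_ascii_grid(path, crs: str = "geographic") -> ResistanceRaster:
    """Read a single-band ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid missing header field {key!r}")
    vals = np.array(rows, dtype=float)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return ResistanceRaster(
        vals,
        (header["xllcorner"], header["yllcorner"]),
        header["cellsize"],
        crs=crs,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: ResistanceRaster, path) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.origin[0]!r}\n")
        fh.write(f"yllcorner {raster.origin[1]!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# least-cost paths
# ---------------------------------------------------------------------------

@dataclass
class LCPResult:
    """A least-cost path and its summary distances."""

    path: list          # ordered (row, col) cells
    length_m: float     # geometric length along cell centres
    accumulated_cost: float
    mean_resistance: float
    weighted_distance: float  # length_m * mean_resistance (== accumulated_cost)


def _grid_graph(raster: ResistanceRaster):
    """Sparse 8-connected graph over valid cells.

    Edge weight = mean of the two cell resistances x centre-to-centre
    distance in metres. Returns (csgraph, node index array with -1 for
    invalid cells, flat list of (row, col) per node, per-edge step lengths
    keyed by (u, v)).
    """
    nrows, ncols = raster.shape
    mask = raster.mask
    node_of = -np.ones((nrows, ncols), dtype=int)
    cells = np.argwhere(mask)
    node_of[mask] = np.arange(len(cells))

    src, dst, wts, steps = [], [], [], []
    vals = raster.values
    for r in range(nrows):
        dx, dy = raster.cell_sizes_m(r)
        diag = math.hypot(dx, dy)
        for c in range(ncols):
            if not mask[r, c]:
                continue
            u = node_of[r, c]
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < nrows and 0 <= cc < ncols) or not mask[rr, cc]:
                    continue
                v = node_of[rr, cc]
                step = dy if dc == 0 else (dx if dr == 0 else diag)
                cost = 0.5 * (vals[r, c] + vals[rr, cc]) * step
                src.append(u)
                dst.append(v)
                wts.append(cost)
                steps.append(step)
    n = len(cells)
    graph = coo_matrix((wts, (src, dst)), shape=(n, n)).tocsr()
    step_m = coo_matrix((steps, (src, dst)), shape=(n, n)).tocsr()
    return graph, node_of, [tuple(c) for c in cells], step_m


def _snap(raster: ResistanceRaster, point, radius: int = 3) -> tuple[int, int]:
    """Nearest valid cell to (x, y) within ``radius`` cells of its cell."""
    r0, c0 = raster.cell_of(*point)
    mask = raster.mask
    if mask[r0, c0]:
        return r0, c0
    best, best_d = None, np.inf
    nrows, ncols = raster.shape
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < nrows and 0 <= c < ncols and mask[r, c]:
                d = dr * dr + dc * dc
                if d < best_d:
                    best, best_d = (r, c), d
    if best is None:
        raise SnapError(f"no valid cell within {radius} cells of {point}")
    return best


def _path_from_predecessors(pred, target):
    path = [target]
    while pred[path[-1]] >= 0:
        path.append(pred[path[-1]])
    return path[::-1]


def _summarise_path(raster, cells_idx, node_path, step_m, costs):
    length = sum(step_m[u, v] for u, v in zip(node_path[:-1], node_path[1:]))
    acc = float(costs)
    mean_res = acc / length if length > 0 else 0.0
    return LCPResult(
        path=[cells_idx[i] for i in node_path],
        length_m=float(length),
        accumulated_cost=acc,
        mean_resistance=float(mean_res),
        weighted_distance=float(length * mean_res),
    )


def least_cost_path(raster: ResistanceRaster, a, b) -> LCPResult:
    """Minimal accumulated-resistance route between two (lon/x, lat/y) points.

    Dijkstra on the 8-connected cell graph; endpoints snap to the nearest
    valid cell within 3 cells. Raises :class:`UnreachableError` if the
    endpoints lie in disjoint components.
    """
    graph, node_of, cells_idx, step_m = _grid_graph(raster)
    ra = _snap(raster, a)
    rb = _snap(raster, b)
    u, v = node_of[ra], node_of[rb]
    costs, pred = dijkstra(graph, directed=False, indices=u, return_predecessors=True)
    if not np.isfinite(costs[v]):
        raise UnreachableError(f"no path between {a} and {b}")
    node_path = _path_from_predecessors(pred, v)
    return _summarise_path(raster, cells_idx, node_path, step_m, costs[v])


def lcp_to_geojson(raster: ResistanceRaster, result: LCPResult) -> dict:
    """A least-cost path as a GeoJSON LineString feature (cell centres)."""
    coords = [list(raster.cell_center(r, c)) for r, c in result.path]
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": {
            "length_m": result.length_m,
            "accumulated_cost": result.accumulated_cost,
            "mean_resistance": result.mean_resistance,
            "weighted_distance": result.weighted_distance,
        },
    }


def geo_distance_matrices(populations, raster: ResistanceRaster | None = None):
    """All pairwise straight-line and weighted-LCP distance matrices.

    ``populations`` maps name -> (lon, lat) or is a list of
    :class:`PopulationGeo`. Returns ``(names, straight, lcp_weighted)``
    where ``lcp_weighted`` is None when no raster is given. Unreachable
    pairs are set to inf with a warning.
    """
    if isinstance(populations, dict):
        names = list(populations)
        coords = [populations[n] for n in names]
    else:
        names = [p.name for p in populations]
        coords = [p.centroid for p in populations]
    n = len(names)
    if n < 2:
        raise ValueError("need at least two populations")

    straight = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            straight[i, j] = straight[j, i] = straight_line_distance(coords[i], coords[j])

    if raster is None:
        return names, straight, None

    graph, node_of, cells_idx, step_m = _grid_graph(raster)
    nodes = [node_of[_snap(raster, c)] for c in coords]
    lcp = np.zeros((n, n))
    for i in range(n):
        costs, pred = dijkstra(graph, directed=False, indices=nodes[i],
                               return_predecessors=True)
        for j in range(i + 1, n):
            if not np.isfinite(costs[nodes[j]]):
                warnings.warn(f"populations {names[i]} and {names[j]} unreachable on raster")
                lcp[i, j] = lcp[j, i] = np.inf
                continue
            node_path = _path_from_predecessors(pred, nodes[j])
            res = _summarise_path(raster, cells_idx, node_path, step_m, costs[nodes[j]])
            lcp[i, j] = lcp[j, i] = res.weighted_distance
    return names, straight, lcp
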