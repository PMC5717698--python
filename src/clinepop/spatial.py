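"""Least-cost marine distances and NMDS re-projection to planar coordinates.

River mouths are snapped to water cells of a regular lat/lon raster in which
land is impassable; pairwise distances are shortest over-water paths on a
water-cell graph (8-neighbour steps plus knight moves, great-circle edge
weights, Dijkstra).  The knight moves keep the grid approximation of
straight-line routes within a few percent even though lat/lon cells are
anisotropic away from the equator.
Non-metric multidimensional scaling then re-projects the distance matrix to
2-D Cartesian coordinates (rank-preserving, Kruskal stress-1), suitable for
downstream spatial analyses that require planar coordinates.

A parametric synthetic coastline generator is included so tests and
simulated studies need no bathymetry: landmasses are axis-aligned lat/lon
boxes rasterized onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.manifold import MDS

__all__ = [
    "CostRaster",
    "Embedding",
    "make_coast_raster",
    "read_ascii_raster",
    "write_ascii_raster",
    "least_cost_distances",
    "nmds_project",
    "great_circle_km",
]

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Haversine great-circle distance in km (array-friendly)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


@dataclass
class CostRaster:
    """Regular lat/lon grid; ``water[i, j]`` True where traversable.

    Row 0 is the southernmost row: cell (i, j) center is at
    (yll + (i + 0.5) * cellsize, xll + (j + 0.5) * cellsize).
    """

    water: np.ndarray      # (nrows, ncols) bool
    xllcorner: float       # lon of the west edge
    yllcorner: float       # lat of the south edge
    cellsize: float        # degrees

    @property
    def nrows(self) -> int:
        return self.water.shape[0]

    @property
    def ncols(self) -> int:
        return self.water.shape[1]

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            self.yllcorner + (i + 0.5) * self.cellsize,
            self.xllcorner + (j + 0.5) * self.cellsize,
        )

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        i = int(np.floor((lat - self.yllcorner) / self.cellsize))
        j = int(np.floor((lon - self.xllcorner) / self.cellsize))
        return i, j

    def contains(self, lat: float, lon: float) -> bool:
        i, j = self.cell_of(lat, lon)
        return 0 <= i < self.nrows and 0 <= j < self.ncols


def make_coast_raster(
    lat_range: tuple[float, float],
    lon_range: tuple[float, float],
    cellsize: float = 0.1,
    land_boxes: list[tuple[float, float, float, float]] = (),
) -> CostRaster:
    """All-water raster over the bounding box, with land boxes stamped in.

    Each land box is (lat_min, lat_max, lon_min, lon_max); cells whose
    centers fall inside become land.
    """
    nrows = int(np.ceil((lat_range[1] - lat_range[0]) / cellsize))
    ncols = int(np.ceil((lon_range[1] - lon_range[0]) / cellsize))
    water = np.ones((nrows, ncols), dtype=bool)
    lat_c = lat_range[0] + (np.arange(nrows) + 0.5) * cellsize
    lon_c = lon_range[0] + (np.arange(ncols) + 0.5) * cellsize
    for la0, la1, lo0, lo1 in land_boxes:
        ri = (lat_c >= la0) & (lat_c <= la1)
        cj = (lon_c >= lo0) & (lon_c <= lo1)
        water[np.ix_(ri, cj)] = False
    return CostRaster(water, lon_range[0], lat_range[0], cellsize)


def write_ascii_raster(raster: CostRaster, path) -> None:
    """Plain ASCII grid: header lines ``key,value`` then the 0/1 water matrix
    (first matrix row = northernmost, as in ESRI ASCII grids)."""
    with open(path, "w") as fh:
        fh.write(f"ncols,{raster.ncols}\n")
        fh.write(f"nrows,{raster.nrows}\n")
        fh.write(f"xllcorner,{raster.xllcorner}\n")
        fh.write(f"yllcorner,{raster.yllcorner}\n")
        fh.write(f"cellsize,{raster.cellsize}\n")
        fh.write("nodata,0\n")
        for row in raster.water[::-1].astype(int):
            fh.write(" ".join(map(str, row)) + "\n")


def read_ascii_raster(path) -> CostRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().strip().split(",")
            header[key] = float(val)
        rows = [list(map(int, line.split())) for line in fh if line.strip()]
    water = np.array(rows, dtype=bool)[::-1]
    return CostRaster(water, header["xllcorner"], header["yllcorner"], header["cellsize"])


def _snap_to_water(raster: CostRaster, lat: float, lon: float,
                   radius: int = 3) -> tuple[int, int]:
    """Nearest water cell within a Chebyshev radius of the containing cell."""
    i0, j0 = raster.cell_of(lat, lon)
    best = None
    best_d = np.inf
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            i, j = i0 + di, j0 + dj
            if 0 <= i < raster.nrows and 0 <= j < raster.ncols and raster.water[i, j]:
                clat, clon = raster.cell_center(i, j)
                d = great_circle_km(lat, lon, clat, clon)
                if d < best_d:
                    best, best_d = (i, j), d
    if best is None:
        raise ValueError(
            f"no water cell within {radius} cells of ({lat:.3f}, {lon:.3f})"
        )
    return best


# undirected forward half of the move set: rook/bishop steps plus knight
# moves.  Knight moves halve the worst-case angular error of the grid
# approximation (important because lat/lon cells are anisotropic away from
# the equator); each knight move requires its two intermediate cells to be
# water so paths cannot jump over a thin land barrier.
_MOVES: list[tuple[int, int, tuple[tuple[int, int], ...]]] = [
    (0, 1, ()),
    (1, 0, ()),
    (1, 1, ()),
    (1, -1, ()),
    (1, 2, ((0, 1), (1, 1))),
    (2, 1, ((1, 0), (1, 1))),
    (1, -2, ((0, -1), (1, -1))),
    (2, -1, ((1, 0), (1, -1))),
]


def _water_graph(raster: CostRaster, knight: bool = True):
    """Sparse graph over water cells with great-circle edge weights."""
    water = raster.water
    nrows, ncols = water.shape
    idx = -np.ones(water.shape, dtype=np.int64)
    wi, wj = np.nonzero(water)
    idx[wi, wj] = np.arange(len(wi))
    lat_c = raster.yllcorner + (np.arange(nrows) + 0.5) * raster.cellsize
    lon_c = raster.xllcorner + (np.arange(ncols) + 0.5) * raster.cellsize

    moves = _MOVES if knight else _MOVES[:4]
    rows, cols, wts = [], [], []
    for di, dj, through in moves:
        si = slice(max(0, -di), nrows - max(0, di))
        sj = slice(max(0, -dj), ncols - max(0, dj))
        ti = slice(max(0, di), nrows - max(0, -di))
        tj = slice(max(0, dj), ncols - max(0, -dj))
        ok = water[si, sj] & water[ti, tj]
        ai, aj = np.nonzero(ok)
        src_i = ai + si.start
        src_j = aj + sj.start
        keep = np.ones(len(src_i), dtype=bool)
        for mi, mj in through:
            keep &= water[src_i + mi, src_j + mj]
        src_i, src_j = src_i[keep], src_j[keep]
        dst_i = src_i + di
        dst_j = src_j + dj
        w = great_circle_km(lat_c[src_i], lon_c[src_j], lat_c[dst_i], lon_c[dst_j])
        rows.append(idx[src_i, src_j])
        cols.append(idx[dst_i, dst_j])
        wts.append(w)
    rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    wts = np.concatenate(wts) if wts else np.array([])
    n = len(wi)
    g = coo_matrix((wts, (rows, cols)), shape=(n, n)).tocsr()
    return g, idx


def least_cost_distances(
    populations: pd.DataFrame,
    raster: CostRaster,
    snap_radius: int = 3,
    knight: bool = True,
) -> pd.DataFrame:
    """Pairwise shortest over-water distances (km) between population coordinates.

    ``populations`` is the metadata table (index = population id, columns
    ``latitude``, ``longitude``).  Each site is snapped to the nearest water
    cell within ``snap_radius`` cells; a site with no nearby water, or a pair
    with no connecting water path, raises.  ``knight=False`` restricts moves
    to the plain 8-neighbour stencil.
    """
    pops = list(populations.index)
    cells = []
    for pop in pops:
        lat = float(populations.loc[pop, "latitude"])
        lon = float(populations.loc[pop, "longitude"])
        if not raster.contains(lat, lon):
            raise ValueError(f"population {pop} outside the raster extent")
        try:
            cells.append(_snap_to_water(raster, lat, lon, snap_radius))
        except ValueError as e:
            raise ValueError(f"population {pop}: {e}") from e
    g, idx = _water_graph(raster, knight=knight)
    # symmetric graph for dijkstra
    g = g + g.T
    sources = np.array([idx[i, j] for i, j in cells])
    dmat = dijkstra(g, directed=False, indices=np.unique(sources))
    row_of = {s: r for r, s in enumerate(np.unique(sources))}
    out = np.zeros((len(pops), len(pops)))
    for a in range(len(pops)):
        for b in range(len(pops)):
            if a == b:
                continue
            d = dmat[row_of[sources[a]], sources[b]]
            if not np.isfinite(d):
                raise ValueError(
                    f"no water path between {pops[a]} and {pops[b]}"
                )
            out[a, b] = d
    out = (out + out.T) / 2  # numerically symmetric
    return pd.DataFrame(out, index=pops, columns=pops)


@dataclass
class Embedding:
    populations: list[str]
    coords: np.ndarray     # (n, dims), centered at the origin
    stress: float          # Kruskal stress-1
    iterations: int

    def frame(self) -> pd.DataFrame:
        cols = [f"axis{k + 1}" for k in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=self.populations, columns=cols)


def nmds_project(
    dist: pd.DataFrame, dims: int = 2, seed: int = 0,
    n_init: int = 4, max_iter: int = 300,
) -> Embedding:
    """Non-metric MDS of a distance matrix to ``dims`` Cartesian axes.

    Kruskal stress-1 minimized by SMACOF with monotone regression on ranks;
    ``n_init`` seeded starts, best stress kept; coordinates re-centered at
    the origin.
    """
    D = dist.to_numpy(float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite entries")
    if len(D) < 3:
        raise ValueError("need at least 3 populations")
    mds = MDS(
        n_components=dims,
        metric_mds=False,
        metric="precomputed",
        normalized_stress=True,
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        eps=1e-9,
    )
    import warnings

    with warnings.catch_warnings():
        # sklearn warns about a future change of the default init; the seeded
        # random starts used here are unaffected
        warnings.filterwarnings("ignore", category=FutureWarning)
        coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    return Embedding(list(dist.index), coords, float(mds.stress_), int(mds.n_iter_))
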