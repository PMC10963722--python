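"""Focal-area inference on a lon/lat raster.

A focal area for a mapped quantity (−K_B for the hub, pBEA for the Basal
homeland) is the set of map locations from which the quantity can only
decrease with distance: for every land cell we compute the shortest overland
distance to each sampled population and the Pearson correlation r between
those distances and the populations' values; strongly negative r marks the
focal area.  Distances run through land cells only, on an 8-connected grid
with great-circle edge lengths, so coastlines and sea barriers are respected.

Rasters are plain ESRI ASCII grids (text); the default working resolution is
0.5°, matching the palaeoclimate grids this kind of analysis is paired with.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import HubseekError, ParseError

EARTH_RADIUS_KM = 6371.0
DEFAULT_RADIUS_KM = 2000.0
SNAP_TOLERANCE_CELLS = 3

_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class Raster:
    """Georeferenced grid; row 0 is the northernmost row (ESRI convention)."""

    values: np.ndarray  # (nrows, ncols)
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        nrows = self.shape[0]
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        nrows, ncols = self.shape
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row = nrows - 1 - int(np.floor((lat - self.yllcorner) / self.cellsize))
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise HubseekError(f"coordinate ({lon}, {lat}) falls outside the raster")
        return row, col

    def lat_of_rows(self) -> np.ndarray:
        nrows = self.shape[0]
        return self.yllcorner + (nrows - 1 - np.arange(nrows) + 0.5) * self.cellsize

    def lon_of_cols(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.shape[1]) + 0.5) * self.cellsize


def read_ascii_grid(path: str | Path) -> Raster:
    lines = Path(path).read_text().splitlines()
    header, i = {}, 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        k, v = lines[i].split()[:2]
        header[k.lower()] = float(v)
        i += 1
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ParseError(f"{path}: missing georeference header field {req!r}")
    values = np.loadtxt(lines[i:], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(f"{path}: data shape {values.shape} does not match header")
    return Raster(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    nrows, ncols = raster.shape
    with open(path, "w") as f:
        f.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {raster.xllcorner}\nyllcorner {raster.yllcorner}\n"
            f"cellsize {raster.cellsize}\nNODATA_value {raster.nodata}\n"
        )
        vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
        np.savetxt(f, vals, fmt="%.6g")


def build_landmask(elevation: Raster, sea_level_offset: float = 0.0) -> Raster:
    """Cell is land iff elevation > sea-level offset (metres; negative offsets
    expose shelf during glacial low stands)."""
    mask = (elevation.values > sea_level_offset).astype(float)
    if mask.sum() == 0:
        import warnings

        warnings.warn("landmask is empty: every cell is below sea level")
    return Raster(
        values=mask,
        xllcorner=elevation.xllcorner,
        yllcorner=elevation.yllcorner,
        cellsize=elevation.cellsize,
        nodata=elevation.nodata,
    )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (array-aware)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def _land_graph(mask: Raster):
    """Sparse 8-connected graph over land cells with great-circle weights.

    Returns (csr graph over land-node indices, node-id raster with -1 at sea).
    """
    land = mask.values > 0
    nrows, ncols = land.shape
    node_id = -np.ones((nrows, ncols), dtype=np.int64)
    node_id[land] = np.arange(land.sum())
    lats = mask.lat_of_rows()
    lons = mask.lon_of_cols()

    src, dst, wts = [], [], []
    for dr, dc in _NEIGHBOURS:
        r0 = max(0, -dr)
        r1 = nrows - max(0, dr)
        c0 = max(0, -dc)
        c1 = ncols - max(0, dc)
        a = land[r0:r1, c0:c1] & land[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        rows, cols = np.nonzero(a)
        rows += r0
        cols += c0
        if rows.size == 0:
            continue
        src.append(node_id[rows, cols])
        dst.append(node_id[rows + dr, cols + dc])
        wts.append(
            haversine_km(lons[cols], lats[rows], lons[cols + dc], lats[rows + dr])
        )
    n = int(land.sum())
    if not src:
        return coo_matrix((n, n)).tocsr(), node_id
    graph = coo_matrix(
        (np.concatenate(wts), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    ).tocsr()
    return graph, node_id


def snap_to_land(mask: Raster, row: int, col: int, tolerance: int = SNAP_TOLERANCE_CELLS):
    """Nearest land cell within ``tolerance`` cells (Chebyshev), else error."""
    land = mask.values > 0
    if land[row, col]:
        return row, col
    nrows, ncols = land.shape
    best, best_d = None, np.inf
    for dr in range(-tolerance, tolerance + 1):
        for dc in range(-tolerance, tolerance + 1):
            r, c = row + dr, col + dc
            if 0 <= r < nrows and 0 <= c < ncols and land[r, c]:
                d = dr * dr + dc * dc
                if d < best_d:
                    best, best_d = (r, c), d
    if best is None:
        raise HubseekError(
            f"no land cell within {tolerance} cells of ({row}, {col}); "
            "sample location cannot be snapped"
        )
    return best


def overland_distance(
    mask: Raster,
    origin: tuple[int, int],
    targets: list[tuple[int, int]],
    snap_targets: bool = True,
) -> np.ndarray:
    """Shortest overland distances (km) from ``origin`` to each target cell.

    The origin must be a land cell; targets are snapped to the nearest land
    cell within tolerance.  Unreachable targets come back as ``inf``."""
    land = mask.values > 0
    if not land[origin]:
        raise HubseekError(f"origin cell {origin} is not on land")
    graph, node_id = _land_graph(mask)
    if snap_targets:
        targets = [snap_to_land(mask, r, c) for r, c in targets]
    else:
        for t in targets:
            if not land[t]:
                raise HubseekError(f"target cell {t} is not on land")
    dist = dijkstra(graph, directed=False, indices=node_id[origin])
    return np.array([dist[node_id[t]] for t in targets])


@dataclass
class FocalSurface:
    r: Raster  # Pearson r per land cell; NaN where masked/ineligible
    n_within: Raster  # number of sampled populations within the radius
    radius_km: float
    locations: pd.DataFrame


def focal_correlation_surface(
    locations: pd.DataFrame,
    mask: Raster,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_within: int = 1,
    restrict_to_radius: bool = False,
) -> FocalSurface:
    """Correlation surface between overland distance and a sampled value.

    ``locations`` needs columns ``population, lon, lat, value``.  For every
    land cell with at least ``min_within`` sampled populations within
    ``radius_km`` overland, the Pearson r between the cell's overland
    distances to ALL sampled populations and their values is computed (the
    radius acts as an eligibility gate; set ``restrict_to_radius`` to
    correlate only within-radius populations instead).  Cells from which some
    population is unreachable overland are masked.
    """
    if len(locations) < 3:
        raise HubseekError("need at least 3 sampled locations for a Pearson r")
    values = locations["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise HubseekError("location values must be finite")
    if np.ptp(values) == 0:
        raise HubseekError("location values have zero variance; r undefined everywhere")

    graph, node_id = _land_graph(mask)
    loc_nodes = []
    for _, row in locations.iterrows():
        r, c = mask.cell_of(float(row["lon"]), float(row["lat"]))
        r, c = snap_to_land(mask, r, c)
        loc_nodes.append(node_id[r, c])
    # one Dijkstra per sampled population: distances to every land cell
    D = dijkstra(graph, directed=False, indices=loc_nodes)  # (n_loc, n_land)

    reachable = np.isfinite(D).all(axis=0)
    within = (D <= radius_km).sum(axis=0)
    eligible = reachable & (within >= min_within)

    n_loc = len(locations)
    r_land = np.full(D.shape[1], np.nan)
    if restrict_to_radius:
        for j in np.flatnonzero(eligible):
            sel = D[:, j] <= radius_km
            if sel.sum() >= 3 and np.ptp(values[sel]) > 0 and np.ptp(D[sel, j]) > 0:
                r_land[j] = np.corrcoef(D[sel, j], values[sel])[0, 1]
    else:
        Dc = D[:, eligible] - D[:, eligible].mean(axis=0)
        vc = values - values.mean()
        denom = np.sqrt((Dc**2).sum(axis=0) * (vc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r_vals = np.where(denom > 0, (Dc * vc[:, None]).sum(axis=0) / denom, np.nan)
        r_land[eligible] = r_vals

    def to_raster(flat: np.ndarray, fill=np.nan) -> Raster:
        grid = np.full(mask.shape, fill)
        grid[mask.values > 0] = flat
        return Raster(
            values=grid,
            xllcorner=mask.xllcorner,
            yllcorner=mask.yllcorner,
            cellsize=mask.cellsize,
            nodata=mask.nodata,
        )

    return FocalSurface(
        r=to_raster(r_land),
        n_within=to_raster(within.astype(float), fill=0.0),
        radius_km=radius_km,
        locations=locations.copy(),
    )


def identify_focal_area(
    surface: FocalSurface, quantile: float = 0.05
) -> tuple[list[tuple[int, int]], tuple[int, int]]:
    """Cells in the lowest-r quantile plus the argmin-r cell."""
    r = surface.r.values
    defined = np.isfinite(r)
    if not defined.any():
        raise HubseekError("focal surface has no defined cells")
    cutoff = np.nanquantile(r[defined], quantile)
    cells = [tuple(ij) for ij in np.argwhere(defined & (r <= cutoff))]
    amin = np.unravel_index(np.nanargmin(np.where(defined, r, np.inf)), r.shape)
    return cells, (int(amin[0]), int(amin[1]))
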