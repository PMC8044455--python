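"""Arc-second analysis grid: cell indexing, spherical areas, concession
overlap and per-cell accumulation of density and area-based services.

The grid is anchored at (-180, -90) with half-open cells
[west, east) x [south, north): a point on a shared edge belongs to the
cell whose west/south edge it lies on. At the default 7.5-arc-second
resolution a cell is ~232 m across and ~5.4 ha at the equator. Cell areas
use the spherical model area = R^2 * dlambda * (sin(phi_n) - sin(phi_s))
with R = 6371 km; polygon overlap uses a local equal-area projection of
the cell, which at this scale is accurate far beyond any decision
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from .inventory import LATA_KG

__all__ = [
    "EARTH_RADIUS_M",
    "GridSpec",
    "cell_area_ha",
    "overlap_fraction",
    "included_cells",
    "rasterize",
    "flag_roads_rivers",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GridSpec:
    """Geographic analysis grid (WGS84 degrees, half-open cells)."""

    resolution_arcsec: float = 7.5
    lon0: float = -180.0
    lat0: float = -90.0

    def __post_init__(self):
        if self.resolution_arcsec <= 0:
            raise ValueError("resolution must be positive")

    @property
    def step(self) -> float:
        """Cell size in decimal degrees."""
        return self.resolution_arcsec / 3600.0

    def cell_of(self, lon, lat):
        """Cell index (ix, iy) of points; ix counts east from the anchor,
        iy north. Vectorized; deterministic under the half-open rule."""
        ix = np.floor((np.asarray(lon, dtype=float) - self.lon0) / self.step).astype(int)
        iy = np.floor((np.asarray(lat, dtype=float) - self.lat0) / self.step).astype(int)
        if np.ndim(lon) == 0:
            return int(ix), int(iy)
        return ix, iy

    def cell_bounds(self, ix, iy):
        """(west, south, east, north) in degrees."""
        w = self.lon0 + np.asarray(ix) * self.step
        s = self.lat0 + np.asarray(iy) * self.step
        return w, s, w + self.step, s + self.step

    def cell_center(self, ix, iy):
        w, s, e, n = self.cell_bounds(ix, iy)
        return (w + e) / 2.0, (s + n) / 2.0


def cell_area_ha(iy, grid: GridSpec) -> float:
    """Ground area of a cell in hectares under the spherical model."""
    _, s, _, n = grid.cell_bounds(0, iy)
    dlam = math.radians(grid.step)
    area_m2 = (
        EARTH_RADIUS_M**2
        * dlam
        * (np.sin(np.radians(n)) - np.sin(np.radians(s)))
    )
    return area_m2 / 1e4


def _equal_area_transform(lat_c: float):
    """Local cylindrical equal-area projection about latitude ``lat_c``
    (metres); exact enough for single-cell overlap fractions."""
    k = math.cos(math.radians(lat_c)) * math.pi / 180.0 * EARTH_RADIUS_M
    m = math.pi / 180.0 * EARTH_RADIUS_M

    def f(coords):
        out = np.asarray(coords, dtype=float).copy()
        out[:, 0] *= k
        out[:, 1] *= m
        return out

    return f


def overlap_fraction(cell: tuple[int, int], polygons, grid: GridSpec | None = None) -> float:
    """Fraction of a cell's area covered by the union of polygons.

    Computed on a local equal-area projection of the cell; 1.0 when the
    cell lies strictly inside the union, 0.0 when disjoint.
    """
    grid = grid or GridSpec()
    w, s, e, n = grid.cell_bounds(*cell)
    cell_geom = box(w, s, e, n)
    geoms = list(polygons.values()) if isinstance(polygons, dict) else list(polygons)
    union = unary_union(geoms)
    inter = cell_geom.intersection(union)
    if inter.is_empty:
        return 0.0
    proj = _equal_area_transform((s + n) / 2.0)
    return shapely.transform(inter, proj).area / shapely.transform(cell_geom, proj).area


def included_cells(
    polygons: dict, grid: GridSpec | None = None, threshold: float = 0.90
) -> pd.DataFrame:
    """All cells whose overlap with the concession union is >= ``threshold``
    (inclusive).

    Returns a frame with ix, iy, overlap_fraction, concession_id (the
    concession contributing the largest share of the cell) and area_ha.
    """
    grid = grid or GridSpec()
    union = unary_union(list(polygons.values()))
    minx, miny, maxx, maxy = union.bounds
    ix0, iy0 = grid.cell_of(minx, miny)
    ix1, iy1 = grid.cell_of(maxx, maxy)
    ixs = np.arange(ix0, ix1 + 1)
    iys = np.arange(iy0, iy1 + 1)
    gx, gy = np.meshgrid(ixs, iys)
    gx, gy = gx.ravel(), gy.ravel()
    w, s, e, n = grid.cell_bounds(gx, gy)
    boxes = shapely.box(w, s, e, n)
    hits = shapely.intersects(boxes, union)
    inside = shapely.contains_properly(union, boxes)

    rows = []
    cids = list(polygons)
    tree = shapely.STRtree(list(polygons.values()))
    for j in np.flatnonzero(hits):
        cell = (int(gx[j]), int(gy[j]))
        frac = 1.0 if inside[j] else overlap_fraction(cell, polygons, grid)
        if frac < threshold:
            continue
        # dominant concession: largest intersection area with the cell box
        cand = tree.query(boxes[j])
        best, best_area = "", -1.0
        for ci in cand:
            a = boxes[j].intersection(polygons[cids[ci]]).area
            if a > best_area:
                best, best_area = cids[ci], a
        rows.append((cell[0], cell[1], frac, best))
    out = pd.DataFrame(rows, columns=["ix", "iy", "overlap_fraction", "concession_id"])
    if len(out):
        out["area_ha"] = [cell_area_ha(iy, grid) for iy in out["iy"]]
        lon_c, lat_c = grid.cell_center(out["ix"].to_numpy(), out["iy"].to_numpy())
        out["lon_c"], out["lat_c"] = lon_c, lat_c
    else:
        for c in ("area_ha", "lon_c", "lat_c"):
            out[c] = pd.Series(dtype=float)
    return out


def rasterize(
    records: pd.DataFrame,
    grid: GridSpec | None = None,
    polygons: dict | None = None,
    threshold: float = 0.90,
    include_empty: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accumulate per-cell tree counts and area-based service sums.

    Returns ``(cells, discarded)``. ``cells`` has one row per included
    cell (overlap >= threshold when polygons are given, else every cell
    containing a tree) with columns n_trees, sp_a_kg, agb_a_kg; absent
    per-tree values contribute zero to the sums but the tree still counts
    toward density. ``discarded`` logs trees falling in excluded cells.
    Zero-tree included cells are retained unless ``include_empty=False``.
    """
    grid = grid or GridSpec()
    ix, iy = grid.cell_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    rec = records.copy()
    rec["ix"], rec["iy"] = ix, iy

    if polygons is not None:
        cells = included_cells(polygons, grid, threshold)
    else:
        uniq = rec[["ix", "iy"]].drop_duplicates()
        cells = uniq.reset_index(drop=True)
        cells["overlap_fraction"] = np.nan
        cells["concession_id"] = ""
        cells["area_ha"] = [cell_area_ha(v, grid) for v in cells["iy"]]
        lon_c, lat_c = grid.cell_center(cells["ix"].to_numpy(), cells["iy"].to_numpy())
        cells["lon_c"], cells["lat_c"] = lon_c, lat_c

    key = pd.MultiIndex.from_frame(cells[["ix", "iy"]])
    rec_key = pd.MultiIndex.from_frame(rec[["ix", "iy"]])
    member = rec_key.isin(key)
    discarded = rec[~member].copy()
    kept = rec[member]

    sp_kg = kept["latas"].fillna(0.0).to_numpy() * LATA_KG
    agb = kept["agb_kg"].fillna(0.0).to_numpy() if "agb_kg" in kept else np.zeros(len(kept))
    agg = pd.DataFrame(
        {"ix": kept["ix"], "iy": kept["iy"], "n": 1, "sp": sp_kg, "agb": agb}
    ).groupby(["ix", "iy"], as_index=False).sum()

    cells = cells.merge(agg, on=["ix", "iy"], how="left")
    cells["n_trees"] = cells.pop("n").fillna(0).astype(int)
    cells["sp_a_kg"] = cells.pop("sp").fillna(0.0)
    cells["agb_a_kg"] = cells.pop("agb").fillna(0.0)
    if not include_empty:
        cells = cells[cells["n_trees"] > 0].reset_index(drop=True)
    cells["road_river"] = 0
    return cells, discarded


def flag_roads_rivers(
    cells: pd.DataFrame, line_features, grid: GridSpec | None = None
) -> pd.DataFrame:
    """Set road_river = 1 for cells whose *closed* rectangle intersects any
    line feature (a touch on the boundary counts for both adjacent cells)."""
    grid = grid or GridSpec()
    out = cells.copy()
    if not len(out) or not line_features:
        out["road_river"] = 0
        return out
    w, s, e, n = grid.cell_bounds(out["ix"].to_numpy(), out["iy"].to_numpy())
    boxes = shapely.box(w, s, e, n)
    lines = unary_union(list(line_features))
    out["road_river"] = shapely.intersects(boxes, lines).astype(int)
    return out
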