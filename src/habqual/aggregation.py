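"""Per-cell nearest-neighbour aggregation index with edge exclusion.

The index is the Clark–Evans ratio R = observed mean nearest-neighbour
distance / expected distance under complete spatial randomness (CSR),
1/(2 sqrt(lambda)) with lambda the cell's point intensity. R < 1 means
aggregated, R = 1 random, R > 1 regular spacing.

Edge effects are handled by exclusion: a point is dropped from the
distance average when it lies closer to the cell boundary than to its
nearest neighbour (its true nearest neighbour could then be outside the
cell). Nearest neighbours are always sought among *all* points of the
cell, before any exclusion.

Plain averaging over the retained points is negatively biased: retention
conditions on small nearest-neighbour distances near edges (Monte Carlo:
mean R ~ 0.92 under CSR at n = 50). The default therefore weights each
retained point by the inverse of its retention probability,
w_i = 1 / |W eroded by d_i| (minus-sampling / Hanisch weighting), which
restores E[R] = 1 under CSR while using exactly the same exclusion rule;
``weighting="plain"`` gives the unweighted mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grids import EARTH_RADIUS_M, GridSpec, cell_area_ha

__all__ = [
    "AggregationResult",
    "nn_distances",
    "edge_filter",
    "aggregation_index",
    "aggregation_map",
    "project_to_cell",
]


@dataclass(frozen=True)
class AggregationResult:
    """Per-cell aggregation summary (distances in metres)."""

    R: float
    n_points: int
    n_retained: int
    mean_nn_m: float
    expected_nn_m: float


def nn_distances(xy: np.ndarray) -> np.ndarray | None:
    """Euclidean nearest-neighbour distance of each point among all the
    others; ``None`` (undefined, not an error) for fewer than two points."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return None
    d, _ = cKDTree(xy).query(xy, k=2)
    return d[:, 1]


def _edge_distances(xy: np.ndarray, bounds) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    x, y = xy[:, 0], xy[:, 1]
    return np.minimum.reduce([x - x0, x1 - x, y - y0, y1 - y])


def edge_filter(xy: np.ndarray, bounds) -> np.ndarray:
    """Boolean retention mask: keep point i iff its distance to the nearest
    cell boundary is >= its nearest-neighbour distance (computed over all
    points, before exclusion). A single point is retained trivially."""
    xy = np.asarray(xy, dtype=float)
    nn = nn_distances(xy)
    if nn is None:
        return np.ones(len(xy), dtype=bool)
    return _edge_distances(xy, bounds) >= nn


def aggregation_index(
    xy: np.ndarray,
    bounds,
    cell_area_m2: float | None = None,
    min_points: int = 2,
    lambda_from: str = "all",
    weighting: str = "hanisch",
) -> AggregationResult | None:
    """Clark–Evans-style aggregation index for one cell.

    ``xy`` are point coordinates in metres, ``bounds`` the cell rectangle
    (x0, y0, x1, y1). The CSR expectation uses the pre-exclusion count by
    default (``lambda_from="retained"`` for sensitivity). Returns ``None``
    when fewer than ``min_points`` points survive the edge filter.
    """
    xy = np.asarray(xy, dtype=float)
    x0, y0, x1, y1 = bounds
    if cell_area_m2 is None:
        cell_area_m2 = (x1 - x0) * (y1 - y0)
    if cell_area_m2 <= 0:
        raise ValueError("cell area must be positive")

    n = len(xy)
    nn = nn_distances(xy)
    if nn is None:
        return None
    keep = _edge_distances(xy, bounds) >= nn
    n_ret = int(keep.sum())
    if n_ret < min_points:
        return None

    if weighting == "hanisch":
        # retention probability of a point with NN distance r is
        # |W eroded by r| / |W|; weight by its inverse
        er = np.maximum(x1 - x0 - 2 * nn, 1e-12) * np.maximum(y1 - y0 - 2 * nn, 1e-12)
        w = 1.0 / er
        mean_nn = float(np.sum((nn * w)[keep]) / np.sum(w[keep]))
    elif weighting == "plain":
        mean_nn = float(nn[keep].mean())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    n_lambda = n if lambda_from == "all" else n_ret
    expected = 1.0 / (2.0 * math.sqrt(n_lambda / cell_area_m2))
    return AggregationResult(mean_nn / expected, n, n_ret, mean_nn, expected)


def project_to_cell(lon, lat, cell: tuple[int, int], grid: GridSpec):
    """Equirectangular projection of points into a cell's local metre
    frame (x east, y north, origin at the cell's SW corner); returns
    (xy, bounds). Distortion at ~232 m cell scale is negligible."""
    w, s, e, n = grid.cell_bounds(*cell)
    lat_c = (s + n) / 2.0
    kx = math.cos(math.radians(lat_c)) * math.pi / 180.0 * EARTH_RADIUS_M
    ky = math.pi / 180.0 * EARTH_RADIUS_M
    x = (np.asarray(lon, dtype=float) - w) * kx
    y = (np.asarray(lat, dtype=float) - s) * ky
    bounds = (0.0, 0.0, (e - w) * kx, (n - s) * ky)
    return np.column_stack([x, y]), bounds


def aggregation_map(
    records,
    cells,
    grid: GridSpec | None = None,
    min_points: int = 2,
    use_ground_area: bool = True,
    **kwargs,
):
    """Attach an ``aggregation`` column to a per-cell table.

    For every included cell with at least ``min_points`` retained trees the
    aggregation index is computed in the cell's local metre frame; other
    cells get NaN (absent, never imputed).
    """
    grid = grid or GridSpec()
    out = cells.copy()
    ix, iy = grid.cell_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    agg = np.full(len(out), np.nan)
    mean_nn = np.full(len(out), np.nan)
    n_ret = np.zeros(len(out), dtype=int)

    groups: dict[tuple[int, int], list[int]] = {}
    for j, key in enumerate(zip(ix, iy)):
        groups.setdefault(key, []).append(j)

    lon = records["lon"].to_numpy()
    lat = records["lat"].to_numpy()
    for row_i, (cx, cy) in enumerate(zip(out["ix"].to_numpy(), out["iy"].to_numpy())):
        idx = groups.get((int(cx), int(cy)))
        if not idx or len(idx) < 2:
            continue
        xy, bounds = project_to_cell(lon[idx], lat[idx], (int(cx), int(cy)), grid)
        area = (
            cell_area_ha(int(cy), grid) * 1e4
            if use_ground_area
            else None
        )
        res = aggregation_index(xy, bounds, cell_area_m2=area,
                                min_points=min_points, **kwargs)
        if res is not None:
            agg[row_i] = res.R
            mean_nn[row_i] = res.mean_nn_m
            n_ret[row_i] = res.n_retained
    out["aggregation"] = agg
    out["mean_nn_m"] = mean_nn
    out["n_retained"] = n_ret
    return out
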