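"""Environmental covariate surfaces: bioclim, soil, terrain.

An :class:`EnvStack` holds named 2-D surfaces co-registered to one
:class:`~habqual.grids.GridSpec` (row 0 of each array is the southernmost
row of the window). Helpers cover the standard preprocessing steps:
depth-weighted 0–100 cm soil means, the Riley root-sum-of-squares terrain
ruggedness index, nearest-cell sampling at tree or cell positions, and
range validation of the resulting covariate table against the study
area's documented gradients.

Raster persistence uses the ESRI ASCII grid text format (one ``.asc``
per surface plus a JSON sidecar naming the grid and layers).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "EnvStack",
    "SOIL_DEPTH_WEIGHTS",
    "SOIL_DEPTH_INTERVALS",
    "depth_weighted_mean",
    "terrain_ruggedness",
    "tri_surface",
    "ENV_RANGES",
    "validate_ranges",
]

#: soil depth intervals (cm) and their 0–100 cm weights (thickness / 100)
SOIL_DEPTH_INTERVALS = ((0, 5), (5, 15), (15, 30), (30, 60), (60, 100))
SOIL_DEPTH_WEIGHTS = (0.05, 0.10, 0.15, 0.30, 0.40)

#: documented environmental gradients of the Madre de Dios Brazil nut
#: study area (min, max); used as default bounds by validate_ranges and
#: as rescaling targets by the synthetic generator.
ENV_RANGES: dict[str, tuple[float, float]] = {
    "bio1": (24.3, 25.6),
    "bio2": (10.6, 11.4),
    "bio3": (66, 75),
    "bio4": (973, 1182),
    "bio5": (31.5, 33.0),
    "bio6": (15.2, 17.6),
    "bio7": (14.2, 16.9),
    "bio8": (25.0, 26.4),
    "bio9": (22.6, 24.0),
    "bio10": (25.2, 26.6),
    "bio11": (22.6, 24.0),
    "bio12": (1794, 3093),
    "bio13": (246, 460),
    "bio14": (28, 104),
    "bio15": (46, 56),
    "bio16": (724, 1268),
    "bio17": (122, 344),
    "bio18": (462, 1150),
    "bio19": (122, 344),
    "sand_pct": (30.7, 54.7),
    "clay_pct": (27.7, 40.6),
    "silt_pct": (14.0, 31.1),
    "bulk_density": (1239.2, 1551.8),
    "org_carbon": (4.05, 31.95),
    "ph": (4.29, 5.48),
    "elevation": (176, 408),
    "slope": (0, 7.5),
    "tri": (0.38, 36.88),
}


@dataclass
class EnvStack:
    """Co-registered covariate surfaces over a rectangular grid window.

    ``origin`` is the (ix, iy) cell index of the array element [0, 0];
    arrays are indexed [row=south->north, col=west->east].
    """

    grid: GridSpec
    origin: tuple[int, int]
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def add(self, name: str, surface: np.ndarray) -> None:
        surface = np.asarray(surface, dtype=float)
        if self.layers and surface.shape != self.shape:
            raise ValueError(
                f"surface {name!r} shape {surface.shape} != stack shape {self.shape}"
            )
        self.layers[name] = surface

    def cell_indices(self, lon, lat):
        """Array indices (row, col) of positions; -1 marks out-of-window."""
        ix, iy = self.grid.cell_of(np.atleast_1d(lon), np.atleast_1d(lat))
        ny, nx = self.shape
        col = ix - self.origin[0]
        row = iy - self.origin[1]
        bad = (col < 0) | (col >= nx) | (row < 0) | (row >= ny)
        col[bad] = -1
        row[bad] = -1
        return row, col

    def sample_at(self, lon, lat, names: list[str] | None = None) -> pd.DataFrame:
        """Nearest-cell covariate values at positions; NaN outside the
        window (an all-outside query warns and returns an all-NaN table)."""
        names = names or self.names
        row, col = self.cell_indices(lon, lat)
        ok = row >= 0
        if len(row) and not ok.any():
            warnings.warn("all positions fall outside the covariate window")
        out = {}
        for name in names:
            vals = np.full(len(row), np.nan)
            vals[ok] = self.layers[name][row[ok], col[ok]]
            out[name] = vals
        return pd.DataFrame(out)

    def centers(self):
        """(lon, lat) arrays of every cell centre, row-major."""
        ny, nx = self.shape
        ix = self.origin[0] + np.arange(nx)
        iy = self.origin[1] + np.arange(ny)
        gx, gy = np.meshgrid(ix, iy)
        return self.grid.cell_center(gx, gy)

    # -- text persistence ---------------------------------------------------
    def to_dir(self, path) -> None:
        """Write one ESRI ASCII grid per surface plus ``stack.json``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ny, nx = self.shape
        w, s, _, _ = self.grid.cell_bounds(*self.origin)
        header = (
            f"ncols {nx}\nnrows {ny}\nxllcorner {w:.12f}\nyllcorner {s:.12f}\n"
            f"cellsize {self.grid.step:.12f}\nNODATA_value -9999\n"
        )
        for name, arr in self.layers.items():
            body = np.flipud(np.where(np.isnan(arr), -9999.0, arr))  # .asc is top-down
            with open(path / f"{name}.asc", "w") as fh:
                fh.write(header)
                np.savetxt(fh, body, fmt="%.10g")
        meta = {
            "resolution_arcsec": self.grid.resolution_arcsec,
            "anchor": [self.grid.lon0, self.grid.lat0],
            "origin": list(self.origin),
            "shape": [ny, nx],
            "layers": self.names,
        }
        (path / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path) -> "EnvStack":
        path = Path(path)
        meta = json.loads((path / "stack.json").read_text())
        grid = GridSpec(meta["resolution_arcsec"], *meta["anchor"])
        stack = cls(grid, tuple(meta["origin"]))
        for name in meta["layers"]:
            arr = np.loadtxt(path / f"{name}.asc", skiprows=6)
            arr = np.flipud(np.atleast_2d(arr))
            arr[arr == -9999.0] = np.nan
            stack.add(name, arr)
        return stack


def depth_weighted_mean(values, renormalize_missing: bool = False):
    """0–100 cm depth-weighted soil mean from the five interval values
    (0–5, 5–15, 15–30, 30–60, 60–100 cm).

    Weights are interval thickness / 100. A missing layer yields NaN
    unless ``renormalize_missing`` re-scales the remaining weights.
    ``values`` may be a length-5 sequence or an array whose last axis has
    length 5.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != 5:
        raise ValueError("expected 5 depth-interval values")
    w = np.asarray(SOIL_DEPTH_WEIGHTS)
    if renormalize_missing:
        mask = ~np.isnan(v)
        ws = np.where(mask, w, 0.0)
        tot = ws.sum(axis=-1)
        with np.errstate(invalid="ignore"):
            out = np.nansum(v * ws, axis=-1) / tot
        out = np.where(tot > 0, out, np.nan)
    else:
        out = (v * w).sum(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def terrain_ruggedness(window) -> float:
    """Riley terrain ruggedness index of a 3x3 elevation window (m):
    root of the summed squared differences between the centre cell and
    its 8 neighbours. NaN for an incomplete window."""
    w = np.asarray(window, dtype=float)
    if w.shape != (3, 3):
        raise ValueError("TRI needs a full 3x3 window")
    if np.isnan(w).any():
        return float("nan")
    diff = w - w[1, 1]
    return float(np.sqrt(np.sum(diff**2)))


def tri_surface(dem: np.ndarray) -> np.ndarray:
    """TRI surface of a DEM; border cells (incomplete window) are NaN."""
    dem = np.asarray(dem, dtype=float)
    out = np.full(dem.shape, np.nan)
    ssq = np.zeros((dem.shape[0] - 2, dem.shape[1] - 2))
    c = dem[1:-1, 1:-1]
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            ssq += (dem[1 + dy : dem.shape[0] - 1 + dy,
                        1 + dx : dem.shape[1] - 1 + dx] - c) ** 2
    out[1:-1, 1:-1] = np.sqrt(ssq)
    return out


def validate_ranges(
    table: pd.DataFrame, ranges: dict[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """Flag covariate values outside their documented [min, max] (bounds
    inclusive). Returns a report frame (variable, index, value, low, high)
    with one row per violation; empty when everything is in range.
    Idempotent and order-independent."""
    ranges = ranges if ranges is not None else ENV_RANGES
    rows = []
    for name, (lo, hi) in sorted(ranges.items()):
        if name not in table.columns:
            continue
        vals = table[name]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        for idx in table.index[bad]:
            rows.append((name, idx, float(vals[idx]), lo, hi))
    return pd.DataFrame(rows, columns=["variable", "index", "value", "low", "high"])
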