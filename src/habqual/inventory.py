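"""Tree-inventory and concession I/O.

Inventories are delimited text tables with one georeferenced tree per row.
In memory they are plain :class:`pandas.DataFrame` objects with canonical
columns::

    tree_id, concession_id, lon, lat, dbh, height, latas, phyto_flags

Optional per-tree fields (dbh, height, latas, phyto_flags) are NaN/empty
when not recorded. A blank production field means "not estimated"; an
explicit 0 means the tree was claimed never to produce — the distinction
carries the non-producer fraction, so the reader never coerces blanks to
zero.

Seed production is recorded in "latas", the harvesters' tin-can unit;
one lata holds approximately 11.66 kg of fresh in-shell seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "LATA_KG",
    "PHYTO_FLAGS",
    "TreeRecord",
    "InventorySummary",
    "InventoryValidationError",
    "read_inventory",
    "write_inventory",
    "filter_min_dbh",
    "latas_to_kg",
    "summarize",
    "read_concessions",
    "read_line_features",
]

#: fresh in-shell seed mass of one lata (tin can), kg
LATA_KG = 11.66

#: recognised phytosanitary condition flags
PHYTO_FLAGS = frozenset(
    {"broken_branches", "tumors", "vines", "holes", "exudate", "termites"}
)

CANONICAL_COLUMNS = (
    "tree_id",
    "concession_id",
    "lon",
    "lat",
    "dbh",
    "height",
    "latas",
    "phyto_flags",
)

MANDATORY = ("tree_id", "concession_id", "lon", "lat")


@dataclass(frozen=True)
class TreeRecord:
    """One inventoried tree (row-level view of the inventory table)."""

    tree_id: str
    concession_id: str
    lon: float
    lat: float
    dbh: float | None = None
    height: float | None = None
    latas: float | None = None
    phyto_flags: frozenset = field(default_factory=frozenset)


class InventoryValidationError(ValueError):
    """Raised when rows violate inventory invariants; lists the rows."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid inventory rows:\n" + "\n".join(problems[:50])
            + ("" if len(problems) <= 50 else f"\n... and {len(problems) - 50} more")
        )


def _to_float(series: pd.Series) -> pd.Series:
    # python float() is correctly rounded (pandas' fast parser is not),
    # so written inventories round-trip bit-identically
    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv).astype(float)


def read_inventory(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited inventory table into canonical form.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"tree_id": "ID", "lon": "X", ...}``; canonical names present in the
    file need no entry. Unparseable *optional* numeric fields become NaN
    (absent), never zero; an unparseable coordinate is a row-level error.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS if column_map.get(c, c) in raw.columns}
    raw = raw.rename(columns=rename)

    missing = [c for c in MANDATORY if c not in raw.columns]
    if missing:
        raise KeyError(f"mandatory inventory column(s) missing: {missing}")

    df = pd.DataFrame(index=raw.index)
    df["tree_id"] = raw["tree_id"].astype(str)
    df["concession_id"] = raw["concession_id"].astype(str)
    for c in ("lon", "lat"):
        df[c] = _to_float(raw[c].replace("", np.nan))
    for c in ("dbh", "height", "latas"):
        df[c] = _to_float(raw[c].replace("", np.nan)) if c in raw.columns else np.nan
    if "phyto_flags" in raw.columns:
        df["phyto_flags"] = raw["phyto_flags"].astype(str)
    else:
        df["phyto_flags"] = ""

    problems = []
    for i in df.index[df["lon"].isna() | df["lat"].isna()]:
        problems.append(f"row {i}: non-numeric or missing coordinate")
    bad_lat = df.index[(df["lat"] < -90) | (df["lat"] > 90)]
    for i in bad_lat:
        problems.append(f"row {i}: latitude {df.at[i, 'lat']} outside [-90, 90]")
    bad_lon = df.index[(df["lon"] < -180) | (df["lon"] > 180)]
    for i in bad_lon:
        problems.append(f"row {i}: longitude {df.at[i, 'lon']} outside [-180, 180]")
    for i in df.index[df["dbh"].notna() & (df["dbh"] <= 0)]:
        problems.append(f"row {i}: non-positive dbh {df.at[i, 'dbh']}")
    for i in df.index[df["latas"].notna() & (df["latas"] < 0)]:
        problems.append(f"row {i}: negative latas {df.at[i, 'latas']}")
    if problems:
        raise InventoryValidationError(problems)
    return df


def write_inventory(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write an inventory table; round-trips finite values bit-identically
    (floats serialised with shortest round-trip repr)."""
    df.to_csv(path, sep=sep, index=False)


def filter_min_dbh(
    df: pd.DataFrame, min_dbh: float = 10.0, keep_missing: bool = True
) -> pd.DataFrame:
    """Retain trees with dbh >= ``min_dbh`` (boundary inclusive).

    Trees without a DBH measurement are retained by default: density
    counts include unmeasured stems.
    """
    if min_dbh <= 0:
        raise ValueError("min_dbh must be positive")
    keep = df["dbh"] >= min_dbh
    if keep_missing:
        keep |= df["dbh"].isna()
    return df[keep]


def latas_to_kg(latas):
    """Convert latas/year to kg/year (1 lata = 11.66 kg fresh in-shell seed)."""
    arr = np.asarray(latas, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("latas must be non-negative")
    out = arr * LATA_KG
    return float(out) if np.isscalar(latas) or arr.ndim == 0 else out


@dataclass(frozen=True)
class InventorySummary:
    """Whole-inventory counts and per-tree seed-production statistics (kg/yr)."""

    n_total: int
    n_with_dbh: int
    n_with_production: int
    sp_mean: float | None
    sp_sd: float | None
    sp_min: float | None
    sp_max: float | None
    zero_producer_fraction: float | None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def summarize(df: pd.DataFrame) -> InventorySummary:
    """Counts plus kg-scale production statistics over production-reporting
    trees; the zero-producer fraction is the share of *reporting* trees with
    latas = 0 (structural non-producers)."""
    n_total = int(len(df))
    n_dbh = int(df["dbh"].notna().sum()) if n_total else 0
    latas = df["latas"].dropna() if n_total else pd.Series(dtype=float)
    n_prod = int(len(latas))
    if n_prod:
        sp = latas.to_numpy() * LATA_KG
        stats = dict(
            sp_mean=float(np.mean(sp)),
            sp_sd=float(np.std(sp, ddof=1)) if n_prod > 1 else 0.0,
            sp_min=float(np.min(sp)),
            sp_max=float(np.max(sp)),
            zero_producer_fraction=float(np.mean(latas.to_numpy() == 0)),
        )
    else:
        stats = dict(sp_mean=None, sp_sd=None, sp_min=None, sp_max=None,
                     zero_producer_fraction=None)
    return InventorySummary(n_total, n_dbh, n_prod, **stats)


# ---------------------------------------------------------------------------
# GeoJSON geometry

class GeometryError(ValueError):
    pass


def _load_geojson_features(path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return gj["features"]
    if gj.get("type") == "Feature":
        return [gj]
    return [{"type": "Feature", "geometry": gj, "properties": {}}]


def read_concessions(path, id_property: str = "concession_id") -> dict[str, BaseGeometry]:
    """Read concession polygons from GeoJSON (WGS84).

    Invalid geometries are repaired with :func:`shapely.make_valid`; a
    geometry that is not polygonal after repair raises
    :class:`GeometryError` naming the offending polygon.
    """
    out: dict[str, BaseGeometry] = {}
    for k, feat in enumerate(_load_geojson_features(path)):
        cid = str(feat.get("properties", {}).get(id_property, k))
        geom = geojson_shape(feat["geometry"])
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
        if geom.is_empty or geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryError(f"concession {cid!r}: not a valid polygon after repair")
        out[cid] = geom
    return out


def read_line_features(path) -> list[BaseGeometry]:
    """Read road/river line features from GeoJSON (WGS84)."""
    geoms = []
    for feat in _load_geojson_features(path):
        geom = geojson_shape(feat["geometry"])
        if geom.geom_type not in ("LineString", "MultiLineString"):
            raise GeometryError(f"expected line feature, got {geom.geom_type}")
        geoms.append(geom)
    return geoms


def records_from_frame(df: pd.DataFrame) -> Iterable[TreeRecord]:
    """Row-level :class:`TreeRecord` view of a canonical inventory frame."""
    for r in df.itertuples(index=False):
        flags = frozenset(f for f in str(r.phyto_flags).split(";") if f in PHYTO_FLAGS)
        yield TreeRecord(
            r.tree_id, r.concession_id, r.lon, r.lat,
            None if pd.isna(r.dbh) else float(r.dbh),
            None if pd.isna(r.height) else float(r.height),
            None if pd.isna(r.latas) else float(r.latas),
            flags,
        )
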