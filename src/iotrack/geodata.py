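"""Reading, writing and linking of GPS, accelerometer and polygon data.

The pipeline operates on pandas DataFrames with fixed schemas:

``GPS fixes`` (one row per raw or imputed GPS record)
    ``t`` (datetime64[ns]), ``lat``, ``lon`` (WGS84 degrees),
    ``source`` ({"observed", "imputed"}), ``noise`` (bool).

``Accelerometer epochs``
    ``t``, ``axis1``, ``axis2``, ``axis3`` (activity counts), ``lux``
    (ambient light, may be NaN).

``Linked track`` (one row per tick of the common epoch grid)
    union of the two schemas plus ``speed_mps``; ticks with no GPS fix
    carry NaN positions so gaps are explicit.

Polygon layers (building footprints, parks) are thin wrappers around
shapely polygons in WGS84.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from shapely.geometry import Polygon, shape

__all__ = [
    "PolygonLayer",
    "round_to_epoch",
    "link_streams",
    "read_gps_csv",
    "read_gpx",
    "read_epoch_csv",
    "read_polygon_layer",
    "read_diary_csv",
    "write_labeled",
    "read_labeled",
]

GPS_COLUMNS = ["t", "lat", "lon", "source", "noise"]
ACC_COLUMNS = ["t", "axis1", "axis2", "axis3", "lux"]
TRACK_COLUMNS = ["t", "lat", "lon", "axis1", "axis2", "axis3", "lux", "speed_mps", "source", "noise"]
LABELED_COLUMNS = ["t", "lat", "lon", "lux", "speed_mps", "cid", "aid", "label", "rule", "imputed"]


@dataclass
class PolygonLayer:
    """A set of simple WGS84 polygons of one kind ("building" or "park")."""

    kind: str
    polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("building", "park"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for i, poly in enumerate(self.polygons):
            if not poly.is_valid:
                raise ValueError(f"polygon {i} in {self.kind} layer is invalid (self-intersecting?)")

    def __len__(self) -> int:
        return len(self.polygons)


def round_to_epoch(t, epoch_s: float = 5):
    """Round timestamps to the nearest multiple of ``epoch_s`` seconds.

    Exact midpoints round up (half-up), so 12:00:02.5 with a 5-s epoch
    becomes 12:00:05.  Accepts a scalar Timestamp or a datetime Series.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    step = int(round(epoch_s * 1e9))
    scalar = not isinstance(t, (pd.Series, pd.DatetimeIndex))
    ts = pd.to_datetime(pd.Series([t]) if scalar else pd.Series(t))
    ns = ts.astype("int64")
    rounded = ((ns + step // 2) // step) * step
    out = pd.to_datetime(rounded)
    return out.iloc[0] if scalar else out


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns {missing}")


def link_streams(fixes: pd.DataFrame, epochs: pd.DataFrame, epoch_s: float = 5) -> pd.DataFrame:
    """Join GPS fixes and accelerometer epochs onto a common epoch grid.

    Both streams are epoch-rounded first.  The output has exactly one row
    per grid tick spanning the union of both streams' time ranges; ticks
    without a GPS fix get NaN positions.  When two fixes round to the same
    tick the earlier raw fix wins.  ``speed_mps`` is left NaN — it is
    filled by :func:`iotrack.preprocess.annotate_speeds`.
    """
    if (fixes is None or len(fixes) == 0) and (epochs is None or len(epochs) == 0):
        raise ValueError("both input streams are empty; nothing to link")
    step = pd.to_timedelta(epoch_s, unit="s")

    parts = []
    if fixes is not None and len(fixes):
        g = fixes.copy()
        _require_columns(g, ["t", "lat", "lon"], "GPS table")
        g["_t_raw"] = pd.to_datetime(g["t"])
        g["t"] = round_to_epoch(g["_t_raw"], epoch_s)
        # collision rule: earlier raw fix wins
        g = g.sort_values("_t_raw", kind="stable").drop_duplicates("t", keep="first")
        g = g.drop(columns="_t_raw").sort_values("t")
        if "source" not in g.columns:
            g["source"] = "observed"
        if "noise" not in g.columns:
            g["noise"] = False
        parts.append(g)
    if epochs is not None and len(epochs):
        a = epochs.copy()
        _require_columns(a, ["t"], "epoch table")
        a["t"] = round_to_epoch(pd.to_datetime(a["t"]), epoch_s)
        a = a.sort_values("t", kind="stable").drop_duplicates("t", keep="first")
        parts.append(a)

    t_min = min(p["t"].iloc[0] for p in parts)
    t_max = max(p["t"].iloc[-1] for p in parts)
    grid = pd.DataFrame({"t": pd.date_range(t_min, t_max, freq=step)})

    out = grid
    for p in parts:
        out = out.merge(p, on="t", how="left")
    for col in TRACK_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out["source"] = out["source"].astype(object).where(out["source"].notna(), "observed")
    out["noise"] = out["noise"].astype(object).where(out["noise"].notna(), False).astype(bool)
    return out[TRACK_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers / writers


def read_gps_csv(
    path,
    time_col: str = "time",
    lat_col: str = "lat",
    lon_col: str = "lon",
) -> pd.DataFrame:
    """Read a GPS track CSV into the fixes schema.

    ``time_col`` may hold ISO-8601 strings or epoch seconds.
    """
    df = pd.read_csv(path)
    _require_columns(df, [time_col, lat_col, lon_col], f"GPS CSV {path}")
    t_raw = df[time_col]
    if pd.api.types.is_numeric_dtype(t_raw):
        t = pd.to_datetime(t_raw, unit="s")
    else:
        t = pd.to_datetime(t_raw)
    out = pd.DataFrame({"t": t, "lat": df[lat_col].astype(float), "lon": df[lon_col].astype(float)})
    bad = out.index[(out["lat"].abs() > 90) | (out["lon"].abs() > 180) | out["lat"].isna()]
    if len(bad):
        raise ValueError(f"GPS CSV {path}: invalid coordinate on data row {bad[0] + 2}")
    out["source"] = "observed"
    out["noise"] = False
    return out


_GPX_NS = {"gpx": "http://www.topografix.com/GPX/1/1"}


def read_gpx(path) -> pd.DataFrame:
    """Read trackpoints (``trkpt``) from a GPX 1.1 file into the fixes schema."""
    tree = etree.parse(str(path))
    rows = []
    pts = tree.findall(".//gpx:trkpt", _GPX_NS) or tree.findall(".//trkpt")
    for pt in pts:
        time_el = pt.find("gpx:time", _GPX_NS)
        if time_el is None:
            time_el = pt.find("time")
        if time_el is None:
            raise ValueError(f"GPX {path}: trkpt without <time> element")
        rows.append((pd.Timestamp(time_el.text).tz_localize(None) if pd.Timestamp(time_el.text).tzinfo is None else pd.Timestamp(time_el.text).tz_convert("UTC").tz_localize(None),
                     float(pt.get("lat")), float(pt.get("lon"))))
    out = pd.DataFrame(rows, columns=["t", "lat", "lon"])
    out["source"] = "observed"
    out["noise"] = False
    return out


def read_epoch_csv(
    path,
    time_col: str = "time",
    axis_cols: Sequence[str] = ("axis1", "axis2", "axis3"),
    lux_col: str = "lux",
) -> pd.DataFrame:
    """Read an ActiLife-style epoch export (counts + lux per epoch)."""
    df = pd.read_csv(path)
    _require_columns(df, [time_col, *axis_cols], f"epoch CSV {path}")
    out = pd.DataFrame({"t": pd.to_datetime(df[time_col])})
    for dst, src in zip(("axis1", "axis2", "axis3"), axis_cols):
        vals = df[src].astype(float)
        if (vals.dropna() < 0).any():
            raise ValueError(f"epoch CSV {path}: negative activity counts in {src}")
        out[dst] = vals
    out["lux"] = df[lux_col].astype(float) if lux_col in df.columns else np.nan
    if (out["lux"].dropna() < 0).any():
        raise ValueError(f"epoch CSV {path}: negative lux values")
    return out


def read_polygon_layer(path, kind: str) -> PolygonLayer:
    """Read a GeoJSON FeatureCollection of polygons (WGS84 required)."""
    with open(path) as fh:
        gj = json.load(fh)
    crs = gj.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", ""))
        if not any(tag in name for tag in ("CRS84", "4326")):
            raise ValueError(f"{path}: GeoJSON CRS {name!r} is not WGS84")
    polys: list[Polygon] = []
    features = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    for feat in features:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type == "Polygon":
            polys.append(geom)
        elif geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            raise ValueError(f"{path}: unsupported geometry type {geom.geom_type}")
    return PolygonLayer(kind=kind, polygons=polys)


def write_polygon_layer(layer: PolygonLayer, path) -> None:
    """Write a polygon layer as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "properties": {"kind": layer.kind},
            "geometry": json.loads(json.dumps(poly.__geo_interface__)),
        }
        for poly in layer.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_diary_csv(path, time_col: str = "start_time", mode_col: str = "mode") -> pd.DataFrame:
    """Read an activity diary (segment start time + true mode)."""
    df = pd.read_csv(path)
    _require_columns(df, [time_col, mode_col], f"diary CSV {path}")
    out = pd.DataFrame({"start": pd.to_datetime(df[time_col]), "mode": df[mode_col].astype(str)})
    bad = set(out["mode"]) - {"indoor", "outdoor", "vehicle"}
    if bad:
        raise ValueError(f"diary CSV {path}: unknown modes {sorted(bad)}")
    return out.sort_values("start").reset_index(drop=True)


def write_labeled(labeled: pd.DataFrame, path) -> None:
    """Write classified epochs as CSV (schema: ``LABELED_COLUMNS``)."""
    out = labeled.copy()
    out["t"] = pd.to_datetime(out["t"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[LABELED_COLUMNS].to_csv(path, index=False)


def read_labeled(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["t"] = pd.to_datetime(df["t"])
    df["imputed"] = df["imputed"].astype(bool)
    return df[LABELED_COLUMNS]
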