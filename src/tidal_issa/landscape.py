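"""Dynamic environmental covariates: wetland raster, elevation, tide, depth.

The habitat map is built by overlaying three vector layers — a base wetland
classification (tidal marsh / other tidal / excluded), an eelgrass layer, and
shellfish-aquaculture infrastructure (polygons and lines) — onto a 10 m grid.
Eelgrass is buffered by 5 m to close gaps between small adjacent patches;
shellfish line features are enclosed in a 1 m buffer and the merged shape is
buffered by a further 1 m to close small interior gaps.  A cell takes the
class of whichever layer covers its center, with precedence
shellfish > eelgrass > base.

Water depth is time-specific: the predicted tide height at a timestamp minus
the cell's elevation.  Negative depths mean the cell stands above the
waterline at that moment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.interpolate import PchipInterpolator
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .grids import (
    CLASS_CODES,
    CLASS_NAMES,
    EXCLUDED,
    ElevationGrid,
    GridGeometry,
    HabitatGrid,
)

BASE_CLASSES = ("tidal_marsh", "other_tidal", "excluded")

_GEOGRAPHIC_CRS_TOKENS = ("4326", "crs84", "wgs 84", "wgs84")


def read_geojson(path: str | Path, class_property: str | None = None):
    """Read a GeoJSON FeatureCollection into shapely geometries.

    Returns a list of geometries, or of ``(geometry, class)`` pairs when
    ``class_property`` names the feature property holding the wetland class.
    Layers must be pre-projected to a planar metric CRS; a file declaring a
    geographic CRS is rejected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    crs_name = str(doc.get("crs", {}).get("properties", {}).get("name", "")).lower()
    if any(tok in crs_name for tok in _GEOGRAPHIC_CRS_TOKENS):
        raise ValueError(
            f"{path}: layer declares geographic CRS {crs_name!r}; "
            "all layers must be pre-projected to a planar metric CRS"
        )
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    out = []
    for feat in feats:
        geom = geojson_shape(feat["geometry"])
        if class_property is None:
            out.append(geom)
        else:
            props = feat.get("properties") or {}
            if class_property not in props:
                raise ValueError(f"feature missing property {class_property!r}")
            out.append((geom, str(props[class_property])))
    return out


def _covers_centers(geom: BaseGeometry | None, cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    if geom is None or geom.is_empty:
        return np.zeros(cx.shape, dtype=bool)
    shapely.prepare(geom)
    return shapely.intersects_xy(geom, cx, cy)


def build_habitat_grid(
    base_layer,
    eelgrass_layer=(),
    shellfish_layer=(),
    cell_size: float = 10.0,
    *,
    eelgrass_buffer: float = 5.0,
    shellfish_buffer: float = 1.0,
    shellfish_closing_buffer: float = 1.0,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> HabitatGrid:
    """Overlay the three vector layers into a categorical grid.

    Parameters
    ----------
    base_layer
        Iterable of ``(geometry, class)`` pairs with class in
        ``{"tidal_marsh", "other_tidal", "excluded"}``.
    eelgrass_layer, shellfish_layer
        Iterables of geometries (shellfish may mix polygons and lines).
    origin, shape
        Optional grid placement ``(x0, y0)`` and ``(nx, ny)``; by default the
        grid snaps to the base layer's bounds.

    A cell's class is decided at its center: shellfish if the buffered
    shellfish shape covers the center, else eelgrass if the buffered eelgrass
    shape covers it, else the base class; centers covered by no base polygon
    (or by an ``excluded`` polygon) are masked out.
    """
    base_layer = list(base_layer)
    if not base_layer:
        raise ValueError("base layer is empty")
    for _, cls in base_layer:
        if cls not in BASE_CLASSES:
            raise ValueError(f"base layer class {cls!r} not in {BASE_CLASSES}")

    eel = unary_union(list(eelgrass_layer)) if list(eelgrass_layer) else None
    if eel is not None and eelgrass_buffer > 0:
        eel = eel.buffer(eelgrass_buffer)

    shell_geoms = list(shellfish_layer)
    shell = None
    if shell_geoms:
        # Line features become 1 m-wide polygons; the merged shape gets one
        # more thin buffer to close interior gaps between adjacent gear.
        buffered = [
            g.buffer(shellfish_buffer) if g.geom_type in ("LineString", "MultiLineString")
            else g
            for g in shell_geoms
        ]
        shell = unary_union(buffered)
        if shellfish_closing_buffer > 0:
            shell = shell.buffer(shellfish_closing_buffer)

    if origin is None or shape is None:
        minx, miny, maxx, maxy = unary_union([g for g, _ in base_layer]).bounds
        x0 = np.floor(minx / cell_size) * cell_size
        y0 = np.floor(miny / cell_size) * cell_size
        nx = max(int(np.ceil((maxx - x0) / cell_size)), 1)
        ny = max(int(np.ceil((maxy - y0) / cell_size)), 1)
    else:
        x0, y0 = origin
        nx, ny = shape
    geom = GridGeometry(x0=x0, y0=y0, cell_size=cell_size, nx=nx, ny=ny)

    cx, cy = geom.cell_centers()
    classes = np.full((ny, nx), EXCLUDED, dtype=np.int8)

    # Base classes first, in listed order (later features win on overlap).
    for g, cls in base_layer:
        hit = _covers_centers(g, cx, cy)
        classes[hit] = EXCLUDED if cls == "excluded" else CLASS_CODES[cls]

    in_study = classes != EXCLUDED
    eel_hit = _covers_centers(eel, cx, cy) & in_study
    classes[eel_hit] = CLASS_CODES["eelgrass"]
    shell_hit = _covers_centers(shell, cx, cy) & in_study
    classes[shell_hit] = CLASS_CODES["shellfish"]  # shellfish > eelgrass

    return HabitatGrid(geom, classes)


def habitat_to_polygons(grid: HabitatGrid) -> dict[str, BaseGeometry]:
    """Dissolve a habitat grid back into one (multi)polygon per class."""
    g = grid.geometry
    out: dict[str, BaseGeometry] = {}
    for name, code in CLASS_CODES.items():
        iy, ix = np.nonzero(grid.classes == code)
        if ix.size == 0:
            continue
        boxes = shapely.box(
            g.x0 + ix * g.cell_size,
            g.y0 + iy * g.cell_size,
            g.x0 + (ix + 1) * g.cell_size,
            g.y0 + (iy + 1) * g.cell_size,
        )
        out[name] = unary_union(boxes)
    return out


def merge_elevation(
    dem: np.ndarray,
    bathymetry: np.ndarray,
    geometry: GridGeometry,
    cutoff: float = 0.0,
    mask: np.ndarray | None = None,
) -> ElevationGrid:
    """Merge DEM and bathymetry into one elevation surface.

    The DEM is authoritative at and above ``cutoff`` (m above MLLW, default
    0); below it the bathymetry layer is used, because LiDAR-derived DEMs do
    not resolve the submerged bed.  NaN marks missing data in either source.
    """
    dem = np.asarray(dem, dtype=float)
    bathymetry = np.asarray(bathymetry, dtype=float)
    if dem.shape != (geometry.ny, geometry.nx) or bathymetry.shape != dem.shape:
        raise ValueError("dem/bathymetry shape does not match geometry")
    use_dem = np.isfinite(dem) & (dem >= cutoff)
    values = np.where(use_dem, dem, bathymetry)
    source = np.where(use_dem, 0, 1).astype(np.int8)
    if mask is None:
        mask = np.ones(dem.shape, dtype=bool)
    missing = mask & ~np.isfinite(values)
    if missing.any():
        iy, ix = np.argwhere(missing)[0]
        raise ValueError(
            f"no elevation source at in-mask cell (row {iy}, col {ix}): "
            "DEM below cutoff and bathymetry missing"
        )
    return ElevationGrid(geometry, values, source)


@dataclass
class TideSeries:
    """Hourly tide predictions (m above MLLW) with subordinate-station offsets.

    ``time_offset_min`` and ``height_offset_m`` are the published corrections
    for a subordinate station, applied additively to the knots before
    interpolation.  Interpolation between the (offset) hourly knots is
    monotone shape-preserving piecewise cubic (PCHIP): it reproduces every
    knot exactly and never overshoots the bracketing knots, and at hourly
    spacing its error is far below tidal amplitude.
    """

    times: pd.DatetimeIndex
    heights: np.ndarray
    time_offset_min: float = 0.0
    height_offset_m: float = 0.0
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        if self.times.tz is not None:
            self.times = self.times.tz_convert("UTC").tz_localize(None)
        self.heights = np.asarray(self.heights, dtype=float)
        if len(self.times) != len(self.heights):
            raise ValueError("times and heights differ in length")
        if len(self.times) < 2:
            raise ValueError("tide series needs at least two knots")
        t = self.times.asi8.astype(float)  # ns since epoch
        if not np.all(np.diff(t) > 0):
            raise ValueError("tide timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("tide heights must be finite")
        knots = (t + self.time_offset_min * 60e9) / 1e9  # seconds
        self._interp = PchipInterpolator(knots, self.heights + self.height_offset_m,
                                         extrapolate=False)
        self._span = (knots[0], knots[-1])

    def with_offsets(self, time_offset_min: float, height_offset_m: float) -> "TideSeries":
        return replace(self, time_offset_min=time_offset_min,
                       height_offset_m=height_offset_m)

    def interpolate(self, t):
        """Tide height (m) at timestamp(s) ``t``; no extrapolation."""
        scalar = np.ndim(t) == 0
        arr = [t] if scalar else list(t)
        ts = pd.DatetimeIndex(pd.to_datetime(arr, utc=True)).tz_localize(None)
        sec = ts.asi8.astype(float) / 1e9
        if sec.min() < self._span[0] or sec.max() > self._span[1]:
            raise ValueError("timestamp outside the tide series span")
        out = self._interp(sec)
        return float(out[0]) if scalar else out

    def interpolate_seconds(self, sec: np.ndarray) -> np.ndarray:
        """Fast path: epoch seconds in, heights out (vectorized)."""
        sec = np.asarray(sec, dtype=float)
        if sec.min() < self._span[0] or sec.max() > self._span[1]:
            raise ValueError("timestamp outside the tide series span")
        return self._interp(sec)


def interpolate_tide(tide: TideSeries, t):
    """Tide height at ``t`` (convenience wrapper around the series method)."""
    return tide.interpolate(t)


def water_depth(x, y, t, elev: ElevationGrid, tide: TideSeries):
    """Time-specific water depth: tide height at ``t`` minus cell elevation.

    The result is a cell-average quantity (the mean depth over the 10 m cell
    containing the point); negative values mean the cell stands above the
    waterline.
    """
    h = tide.interpolate(t)
    z = elev.value_at(x, y)
    return h - z


def read_tide_csv(path: str | Path, *, time_offset_min: float = 0.0,
                  height_offset_m: float = 0.0) -> TideSeries:
    df = pd.read_csv(path)
    for col in ("timestamp", "height_m"):
        if col not in df.columns:
            raise ValueError(f"tide CSV missing column {col!r}")
    times = pd.DatetimeIndex(pd.to_datetime(df["timestamp"], utc=True)).tz_localize(None)
    return TideSeries(times, df["height_m"].to_numpy(dtype=float),
                      time_offset_min=time_offset_min,
                      height_offset_m=height_offset_m)


def write_tide_csv(path: str | Path, tide: TideSeries) -> None:
    pd.DataFrame({
        "timestamp": tide.times.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "height_m": tide.heights,
    }).to_csv(path, index=False)
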