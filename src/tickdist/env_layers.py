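"""Gridded environmental layers: I/O, stacking, terrain derivatives, extraction.

Layers are single-band rasters on a regular WGS84 lat/lon grid with square
cells (the bioclimatic variables Bio1-Bio19 at 5 arc-minutes, plus
elevation and its slope/aspect derivatives). Supported on-disk formats are
ESRI ASCII grid and single-band GeoTIFF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from tickdist.occurrences import OccurrenceSet

M_PER_DEG = 111_320.0  # metres per degree latitude, spherical approximation

PERIOD_LABELS = ("near-current", "2021-2040", "2041-2060", "2061-2080", "2081-2100")


class LayerError(ValueError):
    """Fatal problem with a raster layer or stack."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular square-cell grid in decimal degrees.

    (x_min, y_max) is the outer corner of the upper-left cell; cell (r, c)
    has centre (x_min + (c+0.5)*cell_size, y_max - (r+0.5)*cell_size).
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayerError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise LayerError("cell_size must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_min + (col + 0.5) * self.cell_size,
            self.y_max - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centre coordinate grids, each n_rows x n_cols."""
        lon = self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size
        lat = self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(lon, lat)

    def locate(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (floor rule on edges)."""
        col = math.floor((lon - self.x_min) / self.cell_size)
        row = math.floor((self.y_max - lat) / self.cell_size)
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        r, c = self.locate(lon, lat)
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols


@dataclass
class EnvLayer:
    """One named environmental raster with a validity mask."""

    name: str
    geometry: GridGeometry
    values: np.ndarray  # float array, NaN where masked
    mask: np.ndarray = field(default=None)  # True = valid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise LayerError(
                f"layer {self.name!r}: values shape {self.values.shape} does not "
                f"match geometry ({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.where(self.mask, self.values, np.nan)


@dataclass
class EnvStack:
    """Co-registered layers sharing one geometry and one validity mask."""

    layers: list[EnvLayer]
    period: str = "near-current"
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if not self.layers:
            raise LayerError("stack needs at least one layer")
        if self.period not in PERIOD_LABELS:
            raise LayerError(
                f"unknown period {self.period!r}; allowed: {PERIOD_LABELS}"
            )
        g0 = self.layers[0].geometry
        for lyr in self.layers[1:]:
            if lyr.geometry != g0:
                raise LayerError(
                    f"geometry mismatch between layers "
                    f"{self.layers[0].name!r} and {lyr.name!r}"
                )
        if self.mask is None:
            m = np.ones((g0.n_rows, g0.n_cols), dtype=bool)
            for lyr in self.layers:
                m &= lyr.mask
            self.mask = m
        # shared mask applies to every layer
        for lyr in self.layers:
            lyr.mask = self.mask
            lyr.values = np.where(self.mask, lyr.values, np.nan)

    @property
    def geometry(self) -> GridGeometry:
        return self.layers[0].geometry

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def layer(self, name: str) -> EnvLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise LayerError(f"stack has no layer named {name!r}")

    def subset(self, names: list[str]) -> "EnvStack":
        return EnvStack(
            layers=[self.layer(n) for n in names], period=self.period, mask=self.mask
        )

    def table(self) -> np.ndarray:
        """n_valid x n_layers value matrix over the shared mask (row-major)."""
        return np.column_stack([lyr.values[self.mask] for lyr in self.layers])


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and single-band GeoTIFF

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GDAL_NODATA = 42113


def read_layer(path: str | Path, name: str | None = None) -> EnvLayer:
    """Read an ESRI ASCII grid (.asc) or single-band GeoTIFF (.tif/.tiff).

    The layer name defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise LayerError(f"raster file not found: {path}")
    name = name or path.stem
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(path, name)
    return _read_ascii(path, name)


def _read_ascii(path: Path, name: str) -> EnvLayer:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "dx", "dy", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key == "cellsize" and "cellsize" not in header:
            if "dx" in header and "dy" in header:
                if not math.isclose(header["dx"], header["dy"], rel_tol=1e-9):
                    raise LayerError(f"{path}: non-square cells (dx != dy)")
                header["cellsize"] = header["dx"]
            else:
                raise LayerError(f"{path}: missing cellsize header")
        elif key not in header:
            raise LayerError(f"{path}: missing {key} header")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    if "xllcorner" in header:
        x_min = header["xllcorner"]
    elif "xllcenter" in header:
        x_min = header["xllcenter"] - cell / 2
    else:
        raise LayerError(f"{path}: missing xllcorner/xllcenter")
    if "yllcorner" in header:
        y_min = header["yllcorner"]
    elif "yllcenter" in header:
        y_min = header["yllcenter"] - cell / 2
    else:
        raise LayerError(f"{path}: missing yllcorner/yllcenter")
    data = np.loadtxt(lines[i:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise LayerError(
            f"{path}: data shape {data.shape} != header ({n_rows}, {n_cols})"
        )
    geom = GridGeometry(
        n_rows=n_rows, n_cols=n_cols, x_min=x_min,
        y_max=y_min + n_rows * cell, cell_size=cell, nodata=nodata,
    )
    mask = ~np.isclose(data, nodata, rtol=1e-9, atol=0.0) & np.isfinite(data)
    return EnvLayer(name=name, geometry=geom, values=data, mask=mask)


def write_layer(layer: EnvLayer, path: str | Path) -> None:
    """Write as ESRI ASCII grid or GeoTIFF depending on file extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(layer, path)
        return
    g = layer.geometry
    vals = np.where(layer.mask, layer.values, g.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.x_min!r}\n")
        fh.write(f"yllcorner {g.y_min!r}\n")
        fh.write(f"cellsize {g.cell_size!r}\n")
        fh.write(f"NODATA_value {g.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _read_geotiff(path: Path, name: str) -> EnvLayer:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise LayerError(f"{path}: expected single-band GeoTIFF")
        tags = page.tags
        if _GEOTIFF_PIXELSCALE not in tags or _GEOTIFF_TIEPOINT not in tags:
            raise LayerError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_GEOTIFF_PIXELSCALE].value[:2]
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise LayerError(f"{path}: non-square cells ({sx} x {sy})")
        tie = tags[_GEOTIFF_TIEPOINT].value
        # tiepoint maps raster (i, j) -> model (x, y); standard UL anchoring
        x_min = tie[3] - tie[0] * sx
        y_max = tie[4] + tie[1] * sy
        nodata = -9999.0
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA].value).strip("\x00 "))
    n_rows, n_cols = data.shape
    geom = GridGeometry(
        n_rows=n_rows, n_cols=n_cols, x_min=x_min, y_max=y_max,
        cell_size=sx, nodata=nodata,
    )
    mask = ~np.isclose(data, nodata, rtol=1e-9, atol=0.0) & np.isfinite(data)
    return EnvLayer(name=name, geometry=geom, values=data, mask=mask)


def _write_geotiff(layer: EnvLayer, path: Path) -> None:
    import tifffile

    g = layer.geometry
    vals = np.where(layer.mask, layer.values, g.nodata).astype(np.float64)
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_min, g.y_max, 0.0)),
        (_GDAL_NODATA, "s", 0, str(g.nodata)),
    ]
    tifffile.imwrite(str(path), vals, extratags=extratags)


# ---------------------------------------------------------------------------


def stack_layers(layers: list[EnvLayer], period: str = "near-current") -> EnvStack:
    """Stack co-registered layers; the shared mask is the intersection of
    each layer's valid cells. Geometry must match exactly."""
    return EnvStack(layers=list(layers), period=period)


def resample_nearest(layer: EnvLayer, target: GridGeometry) -> EnvLayer:
    """Regrid a layer to a reference geometry by nearest-neighbour lookup.

    Each target cell takes the value of the source cell containing its
    centre; target cells whose centre falls outside the source extent or on
    a masked source cell are masked.
    """
    lon, lat = target.cell_centers()
    src = layer.geometry
    col = np.floor((lon - src.x_min) / src.cell_size).astype(int)
    row = np.floor((src.y_max - lat) / src.cell_size).astype(int)
    inside = (row >= 0) & (row < src.n_rows) & (col >= 0) & (col < src.n_cols)
    vals = np.full((target.n_rows, target.n_cols), np.nan)
    rr = np.clip(row, 0, src.n_rows - 1)
    cc = np.clip(col, 0, src.n_cols - 1)
    vals[inside] = layer.values[rr[inside], cc[inside]]
    mask = inside & np.isfinite(vals)
    return EnvLayer(name=layer.name, geometry=target, values=vals, mask=mask)


def derive_slope_aspect(elev: EnvLayer) -> tuple[EnvLayer, EnvLayer]:
    """Slope (degrees) and aspect (degrees clockwise from north) from
    elevation in metres, by Horn's 3x3 third-order finite differences.

    Cell spacing in metres comes from latitude (equirectangular: one degree
    of latitude is ~111.32 km; longitude scaled by cos(lat)). Aspect is the
    compass bearing of the downslope direction; flat cells get slope 0 and
    aspect nodata. Border cells are masked.
    """
    g = elev.geometry
    if g.n_rows < 3 or g.n_cols < 3:
        raise LayerError("slope/aspect need a grid of at least 3x3")
    z = elev.values
    _, lat = g.cell_centers()
    dy_m = M_PER_DEG * g.cell_size
    dx_m = M_PER_DEG * g.cell_size * np.cos(np.radians(lat))

    # Horn kernel; rows increase southward so "north" is row-1
    gx = np.full_like(z, np.nan)
    gy = np.full_like(z, np.nan)
    c = np.s_[1:-1]
    gx[c, c] = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * dx_m[c, c])
    gy[c, c] = (
        (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
        - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
    ) / (8 * dy_m)

    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    flat = np.isclose(gx, 0.0, atol=1e-12) & np.isclose(gy, 0.0, atol=1e-12)
    # bearing of (-gx, -gy): downslope direction, clockwise from north
    aspect = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect[flat] = np.nan
    slope[flat & np.isfinite(gx)] = 0.0

    valid = elev.mask & np.isfinite(gx)
    slope_layer = EnvLayer(name="slope", geometry=g, values=slope, mask=valid)
    aspect_mask = valid & ~flat
    aspect_layer = EnvLayer(name="aspect", geometry=g, values=aspect, mask=aspect_mask)
    return slope_layer, aspect_layer


def extract_at_points(stack: EnvStack, points: OccurrenceSet):
    """Values of every stack layer at each occurrence point.

    A point takes the value of the cell containing it (no interpolation);
    points outside the grid or on masked cells are dropped. Returns a
    pandas DataFrame with lon/lat plus one column per layer, and the count
    of dropped points as ``df.attrs['n_dropped']``.
    """
    import pandas as pd

    g = stack.geometry
    rows, cols, keep_lon, keep_lat = [], [], [], []
    n_dropped = 0
    for rec in points:
        r, c = g.locate(rec.lon, rec.lat)
        if 0 <= r < g.n_rows and 0 <= c < g.n_cols and stack.mask[r, c]:
            rows.append(r)
            cols.append(c)
            keep_lon.append(rec.lon)
            keep_lat.append(rec.lat)
        else:
            n_dropped += 1
    if not rows:
        raise LayerError("no occurrence point falls on a valid stack cell")
    data = {"lon": keep_lon, "lat": keep_lat}
    for lyr in stack.layers:
        data[lyr.name] = lyr.values[rows, cols]
    df = pd.DataFrame(data)
    df.attrs["n_dropped"] = n_dropped
    return df
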