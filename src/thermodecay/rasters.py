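"""Gridded-data plumbing: GeoTIFF I/O, grid harmonization, masking, stacking.

Grids are axis-aligned (north-up) with pixel-center registration, row-major
storage and the origin at the top-left corner.  The affine transform is the
standard six-coefficient mapping from (col, row) pixel indices to map
coordinates:

    x = a * col + b * row + c
    y = d * col + e * row + f

with b = d = 0 enforced (no rotation/shear) and e < 0 (rows increase
southward).  In-memory rasters use float64 with NaN as the missing-value
sentinel; on disk they are single-band float32 GeoTIFFs carrying the
transform (ModelPixelScale + ModelTiepoint tags), a CRS citation string and
an explicit nodata tag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

from .decay import DEFAULT_DELTA_T_HOURS, DEFAULT_MIN_PAIRS, estimate_rdk

__all__ = [
    "GridSpec",
    "RasterStack",
    "DecayRateRaster",
    "read_geotiff",
    "write_geotiff",
    "read_stack",
    "write_stack",
    "regrid",
    "mask_by_threshold",
    "rdk_annual_map",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GEO_ASCII_PARAMS = 34737
_GDAL_NODATA = 42113

#: Valid Kelvin LST never drops this low on Earth; smaller values indicate
#: Celsius or unscaled integer input.
KELVIN_FLOOR = 150.0

#: File-side nodata value (NaN in memory).
DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Georeferencing of one raster grid.

    ``transform`` is the (a, b, c, d, e, f) affine described in the module
    docstring; ``nodata`` is the file-side sentinel.
    """

    n_rows: int
    n_cols: int
    transform: tuple = (1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
    crs_label: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0:
            raise ValueError("rotated/sheared transforms are not supported")
        if a == 0 or e == 0:
            raise ValueError("transform is not invertible (zero pixel size)")

    @property
    def shape(self) -> tuple:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_width(self) -> float:
        return abs(self.transform[0])

    @property
    def pixel_height(self) -> float:
        return abs(self.transform[4])

    def pixel_centers(self):
        """(x, y) coordinates of pixel centers as 1-D arrays (cols, rows)."""
        a, _, c, _, e, f = self.transform
        xs = c + a * (np.arange(self.n_cols) + 0.5)
        ys = f + e * (np.arange(self.n_rows) + 0.5)
        return xs, ys

    def index_of(self, x, y):
        """Fractional (row, col) of map coordinates; pixel-center = .5 offset."""
        a, _, c, _, e, f = self.transform
        col = (np.asarray(x, dtype=float) - c) / a
        row = (np.asarray(y, dtype=float) - f) / e
        return row, col

    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax) of the grid extent (pixel edges)."""
        a, _, c, _, e, f = self.transform
        xs = sorted((c, c + a * self.n_cols))
        ys = sorted((f, f + e * self.n_rows))
        return (xs[0], ys[0], xs[1], ys[1])


@dataclass
class RasterStack:
    """Time-indexed stack of single-band rasters sharing one grid.

    ``values`` has shape (n_times, n_rows, n_cols), float64, NaN = missing.
    ``time_labels`` are strictly increasing strings (e.g. composite start
    dates "2005-01-01").
    """

    values: np.ndarray
    grid: GridSpec
    time_labels: Sequence[str]
    variable_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape[1:]} != grid {self.grid.shape}"
            )
        if self.values.shape[0] != len(self.time_labels):
            raise ValueError("one time label per layer required")
        labels = list(self.time_labels)
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ValueError("time_labels must be strictly ordered")
        self.time_labels = labels


@dataclass
class DecayRateRaster:
    """Annual-mean decay rate map with QC support counts.

    ``rdk`` is hr^-1 (NaN where < min_pairs valid pairs); ``n_pairs``
    counts valid contributing pairs per pixel; ``warm_night_fraction`` is
    the scene-wide fraction of valid pairs with T_night > T_day.
    """

    rdk: np.ndarray
    n_pairs: np.ndarray
    grid: GridSpec
    period: str
    warm_night_fraction: float = 0.0


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_extratags(grid: GridSpec):
    a, _, c, _, e, f = grid.transform
    ascii_params = grid.crs_label + "|"
    # Minimal GeoKey directory: version 1.1.0, one key: GTCitation -> ascii
    keys = [1, 1, 0, 1, 1026, _GEO_ASCII_PARAMS, len(ascii_params), 0]
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (abs(a), abs(e), 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)),
        (_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]


def write_geotiff(path, values: np.ndarray, grid: GridSpec) -> None:
    """Write one single-band float32 GeoTIFF; NaN is stored as the nodata tag."""
    arr = np.asarray(values, dtype=np.float32).copy()
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid shape {grid.shape}")
    arr[~np.isfinite(arr)] = np.float32(grid.nodata)
    tifffile.imwrite(str(path), arr, extratags=_geo_extratags(grid))


def read_geotiff(path):
    """Read a single-band GeoTIFF written by this package (or compatible).

    Returns ``(values, grid)`` with nodata mapped to NaN.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(float)
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tiepoint = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = DEFAULT_NODATA
        if _GDAL_NODATA in tags:
            nodata = float(str(tags[_GDAL_NODATA].value).strip("\x00 "))
        crs = "unknown"
        if _GEO_ASCII_PARAMS in tags:
            crs = str(tags[_GEO_ASCII_PARAMS].value).rstrip("|\x00 ")
    sx, sy = float(scale[0]), float(scale[1])
    ox, oy = float(tiepoint[3]), float(tiepoint[4])
    grid = GridSpec(
        n_rows=arr.shape[0],
        n_cols=arr.shape[1],
        transform=(sx, 0.0, ox, 0.0, -sy, oy),
        crs_label=crs,
        nodata=nodata,
    )
    arr = np.where(np.isclose(arr, nodata, equal_nan=False), np.nan, arr)
    return arr, grid


def write_stack(stack: RasterStack, out_dir, prefix: str = "") -> list:
    """Write each layer as ``<prefix><label>.tif``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, layer in zip(stack.time_labels, stack.values):
        p = out_dir / f"{prefix}{label}.tif"
        write_geotiff(p, layer, stack.grid)
        paths.append(p)
    return paths


def read_stack(paths: Sequence, labels: Sequence[str], variable_name: str = "",
               units: str = "", *, kelvin_check: bool = False) -> RasterStack:
    """Read an ordered list of single-band GeoTIFFs into one stack.

    With ``kelvin_check`` enabled, any valid value below ``KELVIN_FLOOR``
    triggers a refusal — the input is likely Celsius or unscaled integers
    (apply the MODIS scale factor before ingest, or use a scale/offset
    config).
    """
    order = np.argsort(labels, kind="stable")
    layers, grid = [], None
    sorted_labels = [labels[i] for i in order]
    for i in order:
        arr, g = read_geotiff(paths[i])
        if grid is None:
            grid = g
        elif g.shape != grid.shape or not np.allclose(g.transform, grid.transform):
            raise ValueError(f"layer {paths[i]} grid differs from first layer")
        if kelvin_check and np.any(arr[np.isfinite(arr)] < KELVIN_FLOOR):
            raise ValueError(
                f"{paths[i]}: values below {KELVIN_FLOOR} K — input may be "
                "Celsius or scaled integers; convert to Kelvin first"
            )
        layers.append(arr)
    return RasterStack(np.stack(layers), grid, sorted_labels, variable_name, units)


# ---------------------------------------------------------------------------
# Regridding


def _overlap_or_raise(source: GridSpec, target: GridSpec) -> None:
    sx0, sy0, sx1, sy1 = source.bounds()
    tx0, ty0, tx1, ty1 = target.bounds()
    if sx1 <= tx0 or tx1 <= sx0 or sy1 <= ty0 or ty1 <= sy0:
        raise ValueError("source and target grids do not overlap")


def regrid(source: RasterStack, target: GridSpec, direction: str = "auto") -> RasterStack:
    """Re-map a stack onto a target grid.

    Coarse-to-fine uses nearest-neighbor assignment of the enclosing source
    pixel; fine-to-coarse uses the mean of valid contributing source pixels
    (nodata excluded, never treated as zero).  ``direction`` is
    ``"nearest"``, ``"mean"``, or ``"auto"`` (mean when the target pixel is
    coarser in area, else nearest).
    """
    _overlap_or_raise(source.grid, target)
    if direction == "auto":
        src_area = source.grid.pixel_width * source.grid.pixel_height
        tgt_area = target.pixel_width * target.pixel_height
        direction = "mean" if tgt_area > src_area else "nearest"
    if direction == "nearest":
        out = _regrid_nearest(source.values, source.grid, target)
    elif direction == "mean":
        out = _regrid_mean(source.values, source.grid, target)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return RasterStack(out, target, source.time_labels,
                       source.variable_name, source.units)


def _regrid_nearest(values, sgrid: GridSpec, tgrid: GridSpec):
    xs, ys = tgrid.pixel_centers()
    rows, cols = sgrid.index_of(xs[None, :], ys[:, None])
    ri = np.floor(rows).astype(int)
    ci = np.floor(cols).astype(int)
    inside = (ri >= 0) & (ri < sgrid.n_rows) & (ci >= 0) & (ci < sgrid.n_cols)
    ri_c = np.clip(ri, 0, sgrid.n_rows - 1)
    ci_c = np.clip(ci, 0, sgrid.n_cols - 1)
    out = values[:, ri_c, ci_c]
    out[:, ~inside] = np.nan
    return out

def _regrid_mean(values, sgrid: GridSpec, tgrid: GridSpec):
    xs, ys = sgrid.pixel_centers()
    rows, cols = tgrid.index_of(xs[None, :], ys[:, None])
    ri = np.floor(rows).astype(int)
    ci = np.floor(cols).astype(int)
    inside = (ri >= 0) & (ri < tgrid.n_rows) & (ci >= 0) & (ci < tgrid.n_cols)
    flat = ri * tgrid.n_cols + ci
    n_cells = tgrid.n_rows * tgrid.n_cols
    out = np.full((values.shape[0],) + tgrid.shape, np.nan)
    for t in range(values.shape[0]):
        layer = values[t]
        ok = inside & np.isfinite(layer)
        sums = np.bincount(flat[ok], weights=layer[ok], minlength=n_cells)
        cnts = np.bincount(flat[ok], minlength=n_cells)
        with np.errstate(invalid="ignore"):
            cell = sums / cnts
        out[t] = cell.reshape(tgrid.shape)
    return out


# ---------------------------------------------------------------------------
# Masking and per-pixel annual decay rate


def mask_by_threshold(stack: RasterStack, mask_raster: np.ndarray,
                      threshold: float, keep: str = ">"):
    """Mask out pixels failing a threshold predicate on an ancillary raster.

    The canonical use is the aridity mask: keep pixels with long-term mean
    annual precipitation strictly above 100 mm yr^-1.  ``keep`` is one of
    ``">"``, ``">="``, ``"<"``, ``"<="``.  Returns ``(masked_stack,
    n_retained)``; pixels where the mask raster is NaN are dropped.
    """
    mask_raster = np.asarray(mask_raster, dtype=float)
    if mask_raster.shape != stack.grid.shape:
        raise ValueError(
            f"mask shape {mask_raster.shape} != stack grid {stack.grid.shape}; "
            "regrid the mask first"
        )
    ops = {">": np.greater, ">=": np.greater_equal,
           "<": np.less, "<=": np.less_equal}
    if keep not in ops:
        raise ValueError(f"keep must be one of {sorted(ops)}")
    with np.errstate(invalid="ignore"):
        keep_mask = ops[keep](mask_raster, threshold) & np.isfinite(mask_raster)
    out = stack.values.copy()
    out[:, ~keep_mask] = np.nan
    n_retained = int(np.count_nonzero(keep_mask))
    return (RasterStack(out, stack.grid, stack.time_labels,
                        stack.variable_name, stack.units), n_retained)


def _year_of(label: str) -> str:
    return str(label)[:4]


def rdk_annual_map(
    day_stack: RasterStack,
    night_stack: RasterStack,
    delta_t: float = DEFAULT_DELTA_T_HOURS,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    year_of=_year_of,
    *,
    mask_warm_nights: bool = False,
) -> dict:
    """Per-pixel annual mean decay rate from paired day/night LST stacks.

    Layers are paired by identical time label; unpaired layers are dropped.
    For each calendar year (``year_of`` maps a label to its grouping key)
    the per-pair rates ln(T_day/T_night)/delta_t are averaged over valid
    pairs, with a companion count raster.  Pixels with fewer than
    ``min_pairs`` valid pairs get NaN.

    Returns an ordered dict ``{year: DecayRateRaster}``.
    """
    if day_stack.grid.shape != night_stack.grid.shape or not np.allclose(
        day_stack.grid.transform, night_stack.grid.transform
    ):
        raise ValueError("day and night stacks are not on the same grid")
    common = sorted(set(day_stack.time_labels) & set(night_stack.time_labels))
    if not common:
        raise ValueError("no common time labels between day and night stacks")
    d_idx = {l: i for i, l in enumerate(day_stack.time_labels)}
    n_idx = {l: i for i, l in enumerate(night_stack.time_labels)}

    out: dict = {}
    for year in sorted({year_of(l) for l in common}):
        labels = [l for l in common if year_of(l) == year]
        day = day_stack.values[[d_idx[l] for l in labels]]
        night = night_stack.values[[n_idx[l] for l in labels]]
        rates = estimate_rdk(day, night, delta_t, warn=False,
                             mask_warm_nights=mask_warm_nights)
        valid = np.isfinite(rates)
        n_pairs = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n_pairs >= max(min_pairs, 1),
                            np.nansum(np.where(valid, rates, 0.0), axis=0)
                            / np.maximum(n_pairs, 1),
                            np.nan)
        both = np.isfinite(day) & np.isfinite(night)
        warm = both & (night > day)
        wfrac = float(warm.sum() / both.sum()) if both.sum() else 0.0
        out[year] = DecayRateRaster(mean, n_pairs.astype(int), day_stack.grid,
                                    period=year, warm_night_fraction=wfrac)
    return out
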