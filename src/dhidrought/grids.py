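"""Georeferenced raster containers and multi-resolution alignment.

Rasters are plain numpy arrays tied to a :class:`GridSpec` (affine transform,
CRS code, nodata value).  GeoTIFF I/O goes through :mod:`tifffile`, writing
the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory, GDAL_NODATA) so files round-trip through any GDAL-based
stack.  Alignment between grids of different resolution is done in index
space and requires a shared CRS; stacks mixing CRSs are rejected rather than
silently reprojected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "GridSpec",
    "CompositeStack",
    "read_raster",
    "write_raster",
    "align_to_grid",
    "binarize_fraction",
]

# GeoTIFF / GDAL private tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Spatial frame of a raster: shape, affine transform, CRS, nodata.

    The affine transform maps (col, row) pixel indices to map coordinates of
    the pixel's *upper-left corner*; cell centers sit half a pixel in.
    ``transform`` is the GDAL-style 6-tuple
    ``(x_origin, x_size, 0, y_origin, 0, -y_size)`` with north-up grids only.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    x_size: float
    y_size: float  # positive; rows advance southwards
    crs_epsg: int = 32632
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.x_size == 0 or self.y_size == 0:
            raise ValueError("pixel sizes must be nonzero")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x_origin + (cols + 0.5) * self.x_size
        y = self.y_origin - (rows + 0.5) * self.y_size
        return np.meshgrid(x, y)

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the half-open grid extent."""
        return (
            self.x_origin,
            self.y_origin - self.n_rows * self.y_size,
            self.x_origin + self.n_cols * self.x_size,
            self.y_origin,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


@dataclasses.dataclass
class CompositeStack:
    """Time-ordered NDVI composites on one grid.

    ``values`` is [time, row, col] in NDVI units ([-1, 1] where valid);
    ``valid`` flags usable cells; ``dates`` are strictly increasing
    ``numpy.datetime64`` composite dates.  This is the container of the
    per-period productivity values p_t that the DHI components summarise.
    """

    values: np.ndarray
    valid: np.ndarray
    dates: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        if self.values.ndim != 3:
            raise ValueError("values must be [time, row, col]")
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")
        if self.values.shape[0] != self.dates.shape[0]:
            raise ValueError("one date per composite required")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("raster shape does not match grid spec")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates) > np.timedelta64(0, "D")):
            raise ValueError("composite dates must be strictly increasing")
        inside = np.abs(self.values[self.valid]) <= 1 + 1e-12
        if inside.size and not inside.all():
            raise ValueError("valid NDVI values must lie in [-1, 1]")

    @property
    def n_composites(self) -> int:
        return int(self.values.shape[0])

    def year(self) -> int:
        years = self.dates.astype("datetime64[Y]").astype(int) + 1970
        uniq = np.unique(years)
        if uniq.size != 1:
            raise ValueError("stack spans more than one calendar year")
        return int(uniq[0])


def _geotiff_extratags(grid: GridSpec) -> list:
    # Minimal GeoKeyDirectory: version 1.1.0, 3 keys -> projected CRS, units
    geokeys = [
        1, 1, 0, 3,
        1024, 0, 1, 1,            # GTModelTypeGeoKey = projected
        1025, 0, 1, 1,            # GTRasterTypeGeoKey = PixelIsArea
        3072, 0, 1, grid.crs_epsg,  # ProjectedCSTypeGeoKey
    ]
    return [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.x_size, grid.y_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), tuple(geokeys)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]


def write_raster(path: str | Path, data: np.ndarray, grid: GridSpec,
                 valid: np.ndarray | None = None) -> Path:
    """Write a single- or multi-band GeoTIFF.

    ``data`` is (rows, cols) or (bands, rows, cols).  Invalid cells are
    filled with the grid's nodata sentinel.
    """
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[1:] != grid.shape:
        raise ValueError(f"data shape {arr.shape[1:]} != grid shape {grid.shape}")
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        if valid.ndim == 2:
            valid = np.broadcast_to(valid, arr.shape)
        arr = np.where(valid, arr, np.float32(grid.nodata))
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        planarconfig="separate" if arr.shape[0] > 1 else None,
        extratags=_geotiff_extratags(grid),
        metadata=None,
    )
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray, GridSpec]:
    """Read a GeoTIFF into (data[bands, rows, cols], valid mask, GridSpec).

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` naming
    the file when georeferencing tags are absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            tags = {t.code: t.value for t in page.tags.values()}
            arr = tif.asarray()
    except Exception as exc:  # unreadable container
        raise ValueError(f"unreadable raster file: {path}: {exc}") from exc
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise ValueError(f"missing georeferencing (GeoTIFF tags) in: {path}")
    scale = tags[_TAG_MODEL_PIXEL_SCALE]
    tie = tags[_TAG_MODEL_TIEPOINT]
    epsg = 32632
    if _TAG_GEO_KEY_DIRECTORY in tags:
        gk = list(tags[_TAG_GEO_KEY_DIRECTORY])
        for i in range(4, len(gk) - 3, 4):
            if gk[i] == 3072:
                epsg = int(gk[i + 3])
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    grid = GridSpec(
        n_rows=arr.shape[1], n_cols=arr.shape[2],
        x_origin=float(tie[3]), y_origin=float(tie[4]),
        x_size=float(scale[0]), y_size=float(scale[1]),
        crs_epsg=epsg, nodata=nodata,
    )
    valid = ~np.isclose(arr, nodata) & np.isfinite(arr)
    return arr, valid, grid


def write_stack(path: str | Path, stack: CompositeStack) -> Path:
    """Write a CompositeStack as a multi-band GeoTIFF plus a JSON sidecar
    holding the composite dates."""
    path = Path(path)
    write_raster(path, stack.values, stack.grid, valid=stack.valid)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "dates": [str(d) for d in stack.dates],
        "grid": stack.grid.to_dict(),
    }, indent=2))
    return path


def read_stack(path: str | Path) -> CompositeStack:
    """Read a multi-band yearly GeoTIFF (with date sidecar) into a stack."""
    arr, valid, grid = read_raster(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        dates = np.array(meta["dates"], dtype="datetime64[D]")
    else:
        raise ValueError(f"missing date sidecar for stack: {sidecar}")
    vals = np.where(valid, arr, 0.0)
    return CompositeStack(values=vals, valid=valid, dates=dates, grid=grid)


def _check_alignable(src_grid: GridSpec, target: GridSpec) -> None:
    if src_grid.crs_epsg != target.crs_epsg:
        raise ValueError(
            f"CRS mismatch (EPSG:{src_grid.crs_epsg} vs EPSG:{target.crs_epsg}); "
            "reproject inputs to a common CRS first"
        )
    sxmin, symin, sxmax, symax = src_grid.bounds()
    txmin, tymin, txmax, tymax = target.bounds()
    if sxmax <= txmin or txmax <= sxmin or symax <= tymin or tymax <= symin:
        raise ValueError("source and target grids do not overlap")


def align_to_grid(data: np.ndarray, src_grid: GridSpec, target: GridSpec,
                  method: str = "bilinear",
                  valid: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Resample a single-band raster onto ``target``.

    Methods: ``bilinear`` (continuous fields, upsampling), ``nearest``
    (categorical), ``mean_aggregate`` (continuous, downsampling) and
    ``fraction`` (binary fine-scale masks -> proportion positive per coarse
    cell).  Cells outside the overlap come back invalid.
    Returns (resampled, valid_mask).
    """
    data = np.asarray(data, dtype=float)
    if data.shape != src_grid.shape:
        raise ValueError("data shape does not match source grid")
    if valid is None:
        valid = np.isfinite(data) & ~np.isclose(data, src_grid.nodata)
    _check_alignable(src_grid, target)

    if method in ("bilinear", "nearest"):
        tx, ty = target.cell_centers()
        # fractional source indices of target cell centers
        col = (tx - src_grid.x_origin) / src_grid.x_size - 0.5
        row = (src_grid.y_origin - ty) / src_grid.y_size - 0.5
        order = 1 if method == "bilinear" else 0
        filled = np.where(valid, data, 0.0)
        out = ndimage.map_coordinates(filled, [row, col], order=order,
                                      mode="nearest")
        wt = ndimage.map_coordinates(valid.astype(float), [row, col],
                                     order=order, mode="nearest")
        inside = (row > -0.5 - 1e-9) & (row < src_grid.n_rows - 0.5 + 1e-9) \
            & (col > -0.5 - 1e-9) & (col < src_grid.n_cols - 0.5 + 1e-9)
        ok = inside & (wt > 0.999)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(ok, out / np.where(wt > 0, wt, 1.0), target.nodata)
        return out, ok

    if method in ("mean_aggregate", "fraction"):
        if method == "fraction":
            vals = valid & (data > 0)
            uniq = np.unique(data[valid])
            if uniq.size and not np.isin(uniq, (0, 1)).all():
                raise ValueError("fraction method requires a binary raster")
            data = vals.astype(float)
        sx, sy = src_grid.cell_centers()
        tcol = np.floor((sx - target.x_origin) / target.x_size).astype(int)
        trow = np.floor((target.y_origin - sy) / target.y_size).astype(int)
        inside = (tcol >= 0) & (tcol < target.n_cols) \
            & (trow >= 0) & (trow < target.n_rows)
        use = inside & valid
        flat = trow[use] * target.n_cols + tcol[use]
        sums = np.bincount(flat, weights=data[use],
                           minlength=target.n_rows * target.n_cols)
        counts = np.bincount(flat, minlength=target.n_rows * target.n_cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / counts
        out = out.reshape(target.shape)
        ok = counts.reshape(target.shape) > 0
        out = np.where(ok, out, target.nodata)
        return out, ok

    raise ValueError(f"unknown resampling method: {method!r}")


def binarize_fraction(fraction: np.ndarray, threshold: float,
                      valid: np.ndarray | None = None) -> np.ndarray:
    """Binary mask: cell positive iff fraction >= threshold (valid cells only)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    fraction = np.asarray(fraction, dtype=float)
    if valid is None:
        valid = np.isfinite(fraction) & (fraction >= 0) & (fraction <= 1)
    bad = valid & ((fraction < 0) | (fraction > 1))
    if bad.any():
        raise ValueError("fraction values must lie in [0, 1]")
    return (fraction >= threshold) & valid
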