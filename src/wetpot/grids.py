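"""Raster grid data model and I/O.

A :class:`Grid` is the universal currency of the pipeline: a single-band
rectangular raster on an equal-area planar system with square cells. Row 0
is north, column 0 is west, and cell ``(r, c)`` addresses its center; all
distances are measured center-to-center.

Two on-disk formats are supported:

* GeoTIFF (``.tif``/``.tiff``) via :mod:`tifffile`, honoring the
  ``ModelPixelScale``, ``ModelTiepoint`` and ``GDAL_NODATA`` tags;
* ESRI ASCII grid (``.asc``), a plain-text format convenient for small
  fixtures and interchange.

Internally, float grids use NaN as the nodata sentinel and integer grids
use ``INT_NODATA``; readers map the file's declared nodata value onto the
sentinel, writers map it back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
from scipy.spatial import cKDTree

INT_NODATA = np.int32(-2147483648)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridError(ValueError):
    """Raised for malformed rasters or misaligned grid operands."""


@dataclass
class Grid:
    """Single-band raster with square cells on a planar grid.

    Parameters
    ----------
    values
        2-D array (rows × cols). Floats use NaN for nodata; integer arrays
        use :data:`INT_NODATA`.
    cell_size
        Cell edge length in meters (> 0; cells are square).
    origin
        ``(x, y)`` map coordinates of the upper-left corner of the upper-left
        cell.
    units
        Free-text label for the cell values ("m", "dB", "%", ...).
    """

    values: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridError(f"grid values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata(self):
        """The internal nodata sentinel for this grid's dtype."""
        return np.nan if np.issubdtype(self.values.dtype, np.floating) else INT_NODATA

    def nodata_mask(self) -> np.ndarray:
        if np.issubdtype(self.values.dtype, np.floating):
            return np.isnan(self.values)
        return self.values == INT_NODATA

    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask()

    def aligned_with(self, other: "Grid") -> bool:
        """True iff shapes, cell size and origin agree exactly."""
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def like(self, values: np.ndarray, units: str | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        return Grid(values, self.cell_size, self.origin,
                    self.units if units is None else units)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    def equals(self, other: "Grid", atol: float = 0.0) -> bool:
        if not self.aligned_with(other):
            return False
        a, b = self.values, other.values
        ma, mb = self.nodata_mask(), other.nodata_mask()
        if not np.array_equal(ma, mb):
            return False
        av = np.asarray(a, dtype=float)[~ma]
        bv = np.asarray(b, dtype=float)[~mb]
        return bool(np.allclose(av, bv, rtol=0.0, atol=atol))


def require_aligned(*grids: Grid, names: tuple[str, ...] | None = None) -> None:
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not ref.aligned_with(g):
            label = names[i] if names else f"grid #{i}"
            raise GridError(f"{label} is not aligned with the reference grid")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_grid(path: str | Path) -> Grid:
    """Read a single-band raster (GeoTIFF or ESRI ASCII grid).

    The file's nodata value is mapped onto the internal sentinel. Raises
    :class:`GridError` for multi-band input or non-square cells.
    """
    path = Path(path)
    if not path.exists():
        raise GridError(f"no such raster: {path}")
    if path.suffix.lower() in {".asc", ".agr"}:
        return _read_asc(path)
    return _read_tif(path)


def write_grid(grid: Grid, path: str | Path, nodata_value: float | int | None = None) -> Path:
    """Write a grid to GeoTIFF or ESRI ASCII, by extension.

    ``nodata_value`` is the sentinel recorded in the file; defaults to
    -9999 for float grids and :data:`INT_NODATA` for integer grids.
    """
    path = Path(path)
    if path.suffix.lower() in {".asc", ".agr"}:
        return _write_asc(grid, path, nodata_value)
    return _write_tif(grid, path, nodata_value)


def _read_tif(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim == 3:
            if data.shape[0] == 1:
                data = data[0]
            elif data.shape[-1] == 1:
                data = data[..., 0]
            else:
                raise GridError(f"multi-band raster not supported: {path}")
        elif data.ndim != 2:
            raise GridError(f"unsupported raster dimensionality {data.ndim}: {path}")

        cell_size, origin = 1.0, (0.0, 0.0)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if not math.isclose(sx, sy, rel_tol=1e-9):
                raise GridError(f"non-square cells ({sx} x {sy}): {path}")
            cell_size = float(sx)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            # tiepoint maps raster (i, j, k) -> model (x, y, z); we only
            # support the upper-left anchored case (i = j = 0)
            origin = (float(tp[3]), float(tp[4]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))

    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float64)
        if nodata is not None and not math.isnan(nodata):
            data[data == nodata] = np.nan
    else:
        data = data.astype(np.int32)
        if nodata is not None:
            data[data == int(nodata)] = INT_NODATA
    return Grid(data, cell_size, origin)


def _write_tif(grid: Grid, path: Path, nodata_value) -> Path:
    import tifffile

    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        nodata_value = -9999.0 if nodata_value is None else float(nodata_value)
        out = np.where(np.isnan(vals), nodata_value, vals).astype(np.float32)
        nodata_str = repr(nodata_value)
    else:
        nodata_value = int(INT_NODATA) if nodata_value is None else int(nodata_value)
        out = np.where(vals == INT_NODATA, nodata_value, vals).astype(np.int32)
        nodata_str = str(nodata_value)

    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
    return path


def _read_asc(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = iter(fh)
        n_header = 0
        data_lines = []
        for line in lines:
            parts = line.split()
            if not parts:
                continue
            if n_header < 6 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                data_lines.append(line)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridError(f"ASCII grid missing '{key}' header: {path}")
    flat = np.array(" ".join(data_lines).split(), dtype=np.float64)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if flat.size != n_rows * n_cols:
        raise GridError(f"ASCII grid has {flat.size} values, expected {n_rows * n_cols}")
    data = flat.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", -9999.0)
    lawful = data[data != nodata]
    integral = (np.all(np.mod(lawful, 1.0) == 0)
                and np.abs(lawful).max(initial=0) < 2**31 - 1)
    cell = header["cellsize"]
    if "xllcorner" in header and "yllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    else:
        origin = (0.0, 0.0)
    if integral:
        out = data.astype(np.int64)
        out[data == nodata] = INT_NODATA
        out = out.astype(np.int32)
    else:
        out = data.copy()
        out[data == nodata] = np.nan
    return Grid(out, cell, origin)


def _write_asc(grid: Grid, path: Path, nodata_value) -> Path:
    vals = grid.values
    is_float = np.issubdtype(vals.dtype, np.floating)
    nodata_value = (-9999.0 if is_float else int(INT_NODATA)) \
        if nodata_value is None else nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1] - grid.n_rows * grid.cell_size:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata_value}\n")
        if is_float:
            out = np.where(np.isnan(vals), nodata_value, vals)
            np.savetxt(fh, out, fmt="%.10g")
        else:
            out = np.where(vals == INT_NODATA, nodata_value, vals)
            np.savetxt(fh, out, fmt="%d")
    return path


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Nodata interpolation
# ---------------------------------------------------------------------------

def fill_nodata(grid: Grid, max_distance: int = 15) -> Grid:
    """Fill nodata holes by inverse-distance-weighted interpolation.

    Each nodata cell with at least one valid cell within ``max_distance``
    cells (Euclidean, center-to-center) receives the IDW (power 1) mean of
    all valid cells within that radius. Cells farther than ``max_distance``
    from any valid cell stay nodata; valid cells are untouched.
    """
    if max_distance < 1:
        raise GridError("max_distance must be >= 1")
    vals = np.asarray(grid.values, dtype=np.float64)
    invalid = grid.nodata_mask()
    if not invalid.any():
        return grid.copy()
    valid_rc = np.argwhere(~invalid)
    hole_rc = np.argwhere(invalid)
    if valid_rc.size == 0:
        return grid.copy()
    tree = cKDTree(valid_rc)
    neighbor_lists = tree.query_ball_point(hole_rc, r=max_distance)
    out = vals.copy()
    vvals = vals[~invalid]
    for (r, c), idx in zip(hole_rc, neighbor_lists):
        if not idx:
            continue
        pts = valid_rc[idx]
        d = np.hypot(pts[:, 0] - r, pts[:, 1] - c)
        w = 1.0 / d
        out[r, c] = np.dot(w, vvals[idx]) / w.sum()
    if np.issubdtype(grid.values.dtype, np.integer):
        filled = np.where(np.isnan(out), INT_NODATA, np.round(out)).astype(grid.values.dtype)
        return grid.like(filled)
    return grid.like(out)


# ---------------------------------------------------------------------------
# Buffered tiling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileSpec:
    """Tiling scheme with an edge buffer to suppress boundary artifacts.

    ``buffer`` is in meters and is converted to whole cells (rounded up)
    at the grid's resolution; the default matches the working buffer used
    for watershed-scale flow-accumulation tiling.
    """

    tile_rows: int
    tile_cols: int
    buffer: float = 6675.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise GridError("tile dimensions must be >= 1")
        if self.buffer < 0:
            raise GridError("buffer must be >= 0")

    def buffer_cells(self, cell_size: float) -> int:
        return int(math.ceil(self.buffer / cell_size))


def iter_tiles(grid: Grid, spec: TileSpec) -> Iterator[tuple[slice, slice, slice, slice]]:
    """Yield (core_rows, core_cols, buf_rows, buf_cols) slices per tile."""
    b = spec.buffer_cells(grid.cell_size)
    for r0 in range(0, grid.n_rows, spec.tile_rows):
        r1 = min(r0 + spec.tile_rows, grid.n_rows)
        for c0 in range(0, grid.n_cols, spec.tile_cols):
            c1 = min(c0 + spec.tile_cols, grid.n_cols)
            br0, br1 = max(0, r0 - b), min(grid.n_rows, r1 + b)
            bc0, bc1 = max(0, c0 - b), min(grid.n_cols, c1 + b)
            yield slice(r0, r1), slice(c0, c1), slice(br0, br1), slice(bc0, bc1)


def tile_and_mosaic(grid: Grid, spec: TileSpec,
                    per_tile: Callable[[Grid], Grid]) -> Grid:
    """Apply ``per_tile`` to each buffered tile, clip, and mosaic.

    ``per_tile`` must return a grid aligned with its input tile. The buffer
    absorbs edge effects of focal/flow operations; results are clipped back
    to the unbuffered tile before mosaicking, so the output is aligned with
    the input grid.
    """
    out: np.ndarray | None = None
    for core_r, core_c, buf_r, buf_c in iter_tiles(grid, spec):
        sub_origin = (grid.origin[0] + buf_c.start * grid.cell_size,
                      grid.origin[1] - buf_r.start * grid.cell_size)
        tile = Grid(grid.values[buf_r, buf_c].copy(), grid.cell_size,
                    sub_origin, grid.units)
        result = per_tile(tile)
        if not result.aligned_with(tile):
            raise GridError("per_tile output is misaligned with its input tile")
        if out is None:
            out = np.full(grid.shape, np.nan if
                          np.issubdtype(result.values.dtype, np.floating)
                          else INT_NODATA, dtype=result.values.dtype)
        rr = slice(core_r.start - buf_r.start, core_r.stop - buf_r.start)
        cc = slice(core_c.start - buf_c.start, core_c.stop - buf_c.start)
        out[core_r, core_c] = result.values[rr, cc]
    assert out is not None
    return grid.like(out)


def focal_mean3(grid: Grid) -> Grid:
    """3×3 focal mean ignoring nodata (used by CTI smoothing and tests).

    Implemented as an explicit 9-term shifted sum in a fixed order, so the
    result for a cell depends only on its 3×3 neighborhood — not on the
    array extent (tiled and untiled computations agree bit-for-bit).
    """
    vals = np.asarray(grid.values, dtype=np.float64)
    nodata = grid.nodata_mask()
    filled = np.where(nodata, 0.0, vals)
    mask = (~nodata).astype(np.float64)
    n_rows, n_cols = grid.shape
    fp = np.zeros((n_rows + 2, n_cols + 2))
    mp = np.zeros((n_rows + 2, n_cols + 2))
    fp[1:-1, 1:-1] = filled
    mp[1:-1, 1:-1] = mask
    s = np.zeros_like(filled)
    n = np.zeros_like(filled)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            s += fp[1 + dr:n_rows + 1 + dr, 1 + dc:n_cols + 1 + dc]
            n += mp[1 + dr:n_rows + 1 + dr, 1 + dc:n_cols + 1 + dc]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, s / n, np.nan)
    out[nodata] = np.nan
    return grid.like(out)
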