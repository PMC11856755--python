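"""Raster data model and ESRI ASCII grid IO.

A :class:`Grid` is a rectangular geographic (lat/lon) raster with an explicit
nodata mask; a :class:`GridStack` is an ordered, spatially aligned collection
of named grids (the carrier for climate layers, suitability surfaces, and
binary maps).  Conventions follow the ESRI ASCII format: the origin is the
*lower-left corner* of the grid, row 0 of ``values`` is the northernmost row,
and a cell owns the half-open interval ``[x, x + cell_size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Grid",
    "GridStack",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "aggregate_resample",
    "cell_area_km2",
    "EARTH_RADIUS_KM",
]

#: Mean Earth radius in km (IUGG).
EARTH_RADIUS_KM = 6371.0088

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class GridFormatError(ValueError):
    """Raised for malformed ESRI ASCII grid files."""


@dataclass
class Grid:
    """A geographic raster with a nodata mask.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values; entries under the mask are ignored.  Row 0 is the
        northernmost row.
    mask : ndarray of bool, same shape
        True marks nodata cells.
    x_origin, y_origin : float
        Longitude/latitude of the lower-left corner, degrees.
    cell_size : float
        Cell edge length in degrees (square cells).
    """

    values: np.ndarray
    mask: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask and values must have identical shape")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("all unmasked values must be finite")
        x1 = self.x_origin + self.n_cols * self.cell_size
        y1 = self.y_origin + self.n_rows * self.cell_size
        if self.x_origin < -180 - 1e-9 or x1 > 180 + 1e-9:
            raise ValueError("longitude extent outside [-180, 180]")
        if self.y_origin < -90 - 1e-9 or y1 > 90 + 1e-9:
            raise ValueError("latitude extent outside [-90, 90]")

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def lon_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, row 0 (north) first."""
        top = self.y_origin + self.n_rows * self.cell_size
        return top - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.mask.copy(), self.x_origin, self.y_origin, self.cell_size)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def rowcol(self, lon, lat):
        """Map coordinates to (row, col) under half-open cell ownership.

        Returns arrays; out-of-extent points get row or col == -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        top = self.y_origin + self.n_rows * self.cell_size
        row = np.floor((top - lat) / self.cell_size).astype(int)
        # points exactly on the top/left edge belong to the first cell
        row = np.where((lat == top), 0, row)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def values_at(self, lon, lat) -> np.ndarray:
        """Cell values at coordinates; NaN outside the extent or on nodata."""
        row, col = self.rowcol(lon, lat)
        out = np.full(np.shape(row), np.nan)
        ok = (row >= 0) & (col >= 0)
        r, c = row[ok], col[ok]
        v = self.values[r, c].astype(float)
        v[self.mask[r, c]] = np.nan
        out[ok] = v
        return out


class GridStack:
    """Ordered, aligned collection of named grids sharing one nodata mask."""

    def __init__(self, layers: Mapping[str, Grid]):
        if not layers:
            raise ValueError("GridStack needs at least one layer")
        self._layers = dict(layers)
        first = next(iter(self._layers.values()))
        for name, g in self._layers.items():
            if not g.aligned_with(first):
                raise ValueError(f"layer {name!r} is not aligned with the stack")
            if not np.array_equal(g.mask, first.mask):
                raise ValueError(f"layer {name!r} has a different nodata mask")

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def template(self) -> Grid:
        return next(iter(self._layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.template.mask

    def __getitem__(self, name: str) -> Grid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    def items(self):
        return self._layers.items()

    def to_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Values of every layer at the given cells, shape (n_cells, n_layers)."""
        return np.column_stack([self._layers[n].values[rows, cols] for n in self.names])

    def unmasked_cells(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.where(~self.mask)
        return rows, cols

    def values_at(self, lon, lat) -> np.ndarray:
        return np.column_stack([self._layers[n].values_at(lon, lat) for n in self.names])

    def subset(self, names: Sequence[str]) -> "GridStack":
        return GridStack({n: self._layers[n] for n in names})


# -- ESRI ASCII IO ----------------------------------------------------------


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    All six header keys (ncols, nrows, xllcorner, yllcorner, cellsize,
    NODATA_value) are required, each exactly once; the payload must contain
    ``nrows`` rows of ``ncols`` numbers.
    """
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            key = tokens[0].lower()
            if not data_lines and key in _HEADER_KEYS:
                if key in header:
                    raise GridFormatError(f"duplicate header key {key!r}")
                if len(tokens) != 2:
                    raise GridFormatError(f"malformed header line for {key!r}")
                header[key] = float(tokens[1])
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridFormatError(f"missing header key(s): {', '.join(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header["nodata_value"]
    rows = []
    for line in data_lines:
        tokens = line.split()
        if len(tokens) != ncols:
            raise GridFormatError(
                f"row length mismatch: expected {ncols} values, got {len(tokens)}"
            )
        rows.append([float(t) for t in tokens])
    if len(rows) != nrows:
        raise GridFormatError(f"expected {nrows} data rows, got {len(rows)}")
    values = np.array(rows, dtype=np.float64)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    g = Grid(values, mask, header["xllcorner"], header["yllcorner"], header["cellsize"])
    g.nodata_value = nodata  # remembered for round-trips
    return g


def write_ascii_grid(grid: Grid, path, nodata_value: float | None = None) -> None:
    """Write a grid as ESRI ASCII text, readable by :func:`read_ascii_grid`.

    Numbers are written with 17 significant digits so the numeric payload
    round-trips bit-exactly.
    """
    if not np.all(np.isfinite(grid.values[~grid.mask])):
        raise ValueError("grid has non-finite unmasked values")
    if nodata_value is None:
        nodata_value = getattr(grid, "nodata_value", -9999.0)
    vals = np.where(grid.mask, nodata_value, grid.values)
    if np.any(vals[~grid.mask] == nodata_value):
        warnings.warn("an unmasked value equals the NODATA sentinel", stacklevel=2)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin:.17g}\n")
        fh.write(f"yllcorner {grid.y_origin:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {nodata_value:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# -- resampling and geometry ------------------------------------------------


def aggregate_resample(grid: Grid, factor: int, method: str = "mean") -> Grid:
    """Coarsen a grid by an integer factor (e.g. 5 for 30 arc-sec -> 2.5 arc-min).

    ``method="mean"`` takes the mean of each factor x factor block's unmasked
    values (a block with no unmasked value stays nodata); ``method="nearest"``
    takes the block's upper-left cell.  Grids whose shape is not divisible by
    the factor are padded with nodata on the south/east edges.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("factor must be a positive integer")
    if method not in ("mean", "nearest"):
        raise ValueError(f"unknown resampling method {method!r}")
    nr, nc = grid.n_rows, grid.n_cols
    pr = (-nr) % factor
    pc = (-nc) % factor
    values, mask = grid.values, grid.mask
    y_origin = grid.y_origin
    if pr or pc:
        warnings.warn(
            f"grid shape ({nr}, {nc}) not divisible by {factor}; padding with nodata",
            stacklevel=2,
        )
        values = np.pad(values, ((0, pr), (0, pc)), constant_values=np.nan)
        mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=True)
        y_origin = grid.y_origin - pr * grid.cell_size  # padded rows extend south
    R, C = values.shape[0] // factor, values.shape[1] // factor
    blocks = np.where(mask, np.nan, values).reshape(R, factor, C, factor)
    if method == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
            out = np.nanmean(blocks, axis=(1, 3))
        out_mask = np.isnan(out)
    else:
        out = blocks[:, 0, :, 0]
        out_mask = np.isnan(out)
    out = np.where(out_mask, np.nan, out)
    return Grid(out, out_mask, grid.x_origin, y_origin, grid.cell_size * factor)


def write_stack(stack: GridStack, directory) -> list[str]:
    """Write every layer of a stack as ``<name>.asc`` in a directory."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, g in stack.items():
        p = os.path.join(directory, f"{name}.asc")
        write_ascii_grid(g, p)
        paths.append(p)
    return paths


def read_stack(directory, names: Sequence[str] | None = None) -> GridStack:
    """Read a stack of ``.asc`` layers from a directory (all, or by name)."""
    import glob
    import os

    if names is None:
        paths = sorted(glob.glob(os.path.join(directory, "*.asc")))
        names = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    return GridStack({n: read_ascii_grid(os.path.join(directory, f"{n}.asc")) for n in names})


def cell_area_km2(grid: Grid) -> Grid:
    """Per-cell spherical surface area in km^2.

    Area of a cell spanning longitudes of width dlon and latitudes
    [phi_bottom, phi_top] is R^2 * dlon * (sin phi_top - sin phi_bottom);
    it depends only on the latitude band.
    """
    dlon = np.deg2rad(grid.cell_size)
    top = grid.y_origin + grid.n_rows * grid.cell_size
    lat_top = np.deg2rad(top - np.arange(grid.n_rows) * grid.cell_size)
    lat_bot = lat_top - np.deg2rad(grid.cell_size)
    band = EARTH_RADIUS_KM**2 * dlon * (np.sin(lat_top) - np.sin(lat_bot))
    values = np.repeat(band[:, None], grid.n_cols, axis=1)
    return Grid(values, np.zeros_like(values, dtype=bool), grid.x_origin, grid.y_origin, grid.cell_size)
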