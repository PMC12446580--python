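"""Raster container and plain-text raster I/O.

All gridded quantities in the pipeline (climate layers, landcover codes,
distances, suitability, resistance, current, z-scores) live in a single
:class:`Raster` type: a rectangular 2-D array with a cell size in metres,
a lower-left origin and a nodata sentinel.  Row 0 is the *northern* edge
of the grid, matching the usual raster convention.

On disk rasters are ESRI ASCII grids (``.asc``), a plain-text format
every GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["Raster", "RasterStack", "read_ascii", "write_ascii"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular grid of values with simple georeferencing.

    Parameters
    ----------
    values
        2-D array, float or integer category codes.  Row 0 is the top
        (northern) row.
    cell_size
        Edge length of one cell in metres; must be positive.
    origin
        ``(x0, y0)`` of the lower-left corner of the grid in metres.
    nodata
        Sentinel marking missing cells.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "Raster", *, tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of non-nodata, finite cells."""
        vals = self.values.astype(float, copy=False)
        mask = np.isfinite(vals)
        if self.nodata is not None:
            mask &= vals != self.nodata
        return mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    # -- coordinate transforms -------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing ``(x, y)``; raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(self.n_rows - 1 - np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) falls outside the raster extent")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        w = self.n_cols * self.cell_size
        h = self.n_rows * self.cell_size
        return x0 <= x < x0 + w and y0 <= y < y0 + h

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    # -- convenience ------------------------------------------------------

    def copy_with(self, values: np.ndarray) -> "Raster":
        """New raster with the same geometry but different values."""
        return replace(self, values=np.asarray(values))

    def astype(self, dtype) -> "Raster":
        return self.copy_with(self.values.astype(dtype))


@dataclass
class RasterStack:
    """An ordered, named collection of co-registered rasters."""

    layers: list[Raster]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"layer_{i}" for i in range(len(self.layers))]
        if len(self.names) != len(self.layers):
            raise ValueError("names and layers length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if self.layers:
            ref = self.layers[0]
            for name, lyr in zip(self.names, self.layers):
                if not lyr.same_geometry(ref):
                    raise ValueError(f"layer {name!r} geometry differs from first layer")

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[self.names.index(name)]

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names], list(names))

    def as_array(self) -> np.ndarray:
        """(n_layers, n_rows, n_cols) float array."""
        return np.stack([lyr.values.astype(float) for lyr in self.layers])

    def joint_valid_mask(self) -> np.ndarray:
        mask = self.layers[0].valid_mask()
        for lyr in self.layers[1:]:
            mask &= lyr.valid_mask()
        return mask

    @property
    def geometry(self) -> Raster:
        return self.layers[0]


# -- ESRI ASCII grid I/O ---------------------------------------------------


def write_ascii(raster: Raster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid."""
    path = Path(path)
    vals = np.asarray(raster.values, dtype=float)
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii` (or any GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {vals.shape} does not match header ({n_rows}, {n_cols})")
    return Raster(
        values=vals,
        cell_size=header.get("cellsize", 1.0),
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
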