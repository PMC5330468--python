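"""Minimal 2-D raster container used throughout the pipeline.

A :class:`RasterGrid` is a north-up regular grid on a local metric
coordinate system: row 0 is the northern edge, ``origin`` is the
(x, y) of the *top-left corner*, and cell centers sit at half-cell
offsets.  Continuous grids are float arrays with NaN as nodata;
categorical grids are integer arrays with an explicit ``nodata``
sentinel.

Grids are read and written as ESRI ASCII grid text files (``.asc``),
which keeps every artifact human-diffable and GIS-loadable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class RasterGrid:
    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_aligned(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"raster geometry mismatch: {self.shape}@{self.cell_size} vs "
                f"{other.shape}@{other.cell_size}"
            )

    def cell_at(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing point (x, y); half-open cell intervals."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_at(x, y)
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def xy_of(self, row: int, col: int) -> tuple[float, float]:
        """Center coordinates of cell (row, col)."""
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] - (row + 0.5) * self.cell_size
        return x, y

    # -- values -----------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating):
            mask &= ~np.isnan(self.data)
        if self.nodata is not None:
            mask &= self.data != self.nodata
        return mask

    def with_data(self, data: np.ndarray, nodata: float | int | None = None) -> "RasterGrid":
        out = replace(self, data=np.asarray(data))
        out.nodata = nodata
        return out

    def copy(self) -> "RasterGrid":
        return replace(self, data=self.data.copy())


def write_ascii_grid(grid: RasterGrid, path: str, fmt: str = "%.8g") -> None:
    nodata = grid.nodata
    data = grid.data
    if np.issubdtype(data.dtype, np.floating):
        nodata = -9999.0 if nodata is None else nodata
        data = np.where(np.isnan(data), nodata, data)
    elif nodata is None:
        nodata = -9999
    x0, y_top = grid.origin
    yll = y_top - grid.n_rows * grid.cell_size
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {yll}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt=fmt)


def read_ascii_grid(path: str, dtype=np.float64) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=dtype)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value")
    if np.issubdtype(np.dtype(dtype), np.floating) and nodata is not None:
        data = np.where(data == nodata, np.nan, data)
        nodata = None
    cell = header["cellsize"]
    y_top = header["yllcorner"] + header["nrows"] * cell
    return RasterGrid(
        data=data,
        cell_size=cell,
        origin=(header["xllcorner"], y_top),
        nodata=None if nodata is None else dtype(nodata),
    )
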