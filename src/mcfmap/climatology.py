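"""Ground-fog frequency climatologies from per-scene fog masks.

Each satellite scene is a grid of codes {CLEAR, FOG, INVALID} tagged
with its calendar month.  The monthly frequency at a cell is
``#FOG / (#FOG + #CLEAR)`` over that month's scenes — invalid
retrievals (e.g. optically thick cloud where ground fog cannot be
decided) are excluded from numerator *and* denominator, because
counting them as clear would bias frequencies low.  Cells with fewer
valid observations than ``min_valid_threshold`` are nodata.

The annual frequency is the valid-count-weighted mean of the monthly
frequencies, which is identical to pooling all scenes of the year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["CLEAR", "FOG", "INVALID", "FogMaskSeries", "FogClimatology",
           "build_climatology", "frequency_by_altitude_band"]

logger = logging.getLogger(__name__)

CLEAR = 0
FOG = 1
INVALID = 255
_CODES = frozenset({CLEAR, FOG, INVALID})


@dataclass
class FogMaskSeries:
    """Stack of per-scene observation grids with calendar-month tags."""

    codes: np.ndarray  # (n_scenes, rows, cols) uint8
    months: np.ndarray  # (n_scenes,) int in 1..12
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        self.months = np.asarray(self.months, dtype=int)
        if self.codes.ndim != 3:
            raise ValueError("codes must be (n_scenes, rows, cols)")
        if len(self.months) != self.codes.shape[0]:
            raise ValueError("one month tag per scene required")
        if self.months.size and not (
            (self.months >= 1).all() and (self.months <= 12).all()
        ):
            raise ValueError("months must be in 1..12")
        present = set(np.unique(self.codes)) if self.codes.size else set()
        if not present <= _CODES:
            raise ValueError(f"invalid observation codes: {sorted(present - _CODES)}")

    @property
    def n_scenes(self) -> int:
        return self.codes.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.codes.shape[1:]

    def concat(self, other: "FogMaskSeries") -> "FogMaskSeries":
        if self.grid_shape != other.grid_shape:
            raise ValueError("cannot concatenate series with different grids")
        return FogMaskSeries(
            codes=np.concatenate([self.codes, other.codes]),
            months=np.concatenate([self.months, other.months]),
            cell_size=self.cell_size,
            origin=self.origin,
        )


@dataclass
class FogClimatology:
    monthly_frequency: list[RasterGrid]  # 12 grids, NaN below the valid floor
    annual_frequency: RasterGrid
    monthly_valid_counts: list[RasterGrid]  # 12 integer grids
    min_valid_threshold: int


def build_climatology(series: FogMaskSeries, min_valid_threshold: int = 10) -> FogClimatology:
    """Monthly and annual fog frequency with valid-observation accounting."""
    if series.n_scenes == 0:
        raise ValueError("empty fog-mask series")
    if min_valid_threshold < 1:
        raise ValueError("min_valid_threshold must be >= 1")
    shape = series.grid_shape
    geom = dict(cell_size=series.cell_size, origin=series.origin)

    monthly_f: list[RasterGrid] = []
    monthly_n: list[RasterGrid] = []
    fog_weighted = np.zeros(shape)
    n_total = np.zeros(shape, dtype=np.int64)
    for month in range(1, 13):
        scenes = series.codes[series.months == month]
        if scenes.shape[0] == 0:
            logger.info("month %d has no scenes; all-nodata frequency", month)
            fog_count = np.zeros(shape, dtype=np.int64)
            n_valid = np.zeros(shape, dtype=np.int64)
        else:
            fog_count = (scenes == FOG).sum(axis=0)
            n_valid = (scenes != INVALID).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = fog_count / n_valid
        f[n_valid < min_valid_threshold] = np.nan
        monthly_f.append(RasterGrid(data=f, **geom))
        monthly_n.append(RasterGrid(data=n_valid, **geom))
        defined = n_valid >= min_valid_threshold
        fog_weighted[defined] += fog_count[defined]
        n_total[defined] += n_valid[defined]

    with np.errstate(invalid="ignore", divide="ignore"):
        annual = fog_weighted / n_total
    annual[n_total == 0] = np.nan
    return FogClimatology(
        monthly_frequency=monthly_f,
        annual_frequency=RasterGrid(data=annual, **geom),
        monthly_valid_counts=monthly_n,
        min_valid_threshold=min_valid_threshold,
    )


def frequency_by_altitude_band(
    clim: FogClimatology, dem: RasterGrid, band_edges
) -> pd.DataFrame:
    """Mean annual fog frequency per altitude band ``[lower, upper)``."""
    edges = [float(e) for e in band_edges]
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("band_edges must be >= 2 ascending values")
    dem.require_aligned(clim.annual_frequency)
    alt = np.asarray(dem.data, dtype=float)
    freq = np.asarray(clim.annual_frequency.data, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (alt >= lo) & (alt < hi) & ~np.isnan(freq) & ~np.isnan(alt)
        rows.append(
            {
                "lower_m": lo,
                "upper_m": hi,
                "n_cells": int(sel.sum()),
                "mean_frequency": float(freq[sel].mean()) if sel.any() else np.nan,
                "missing": not bool(sel.any()),
            }
        )
    return pd.DataFrame(rows)
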