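"""Final map products: intersection of the conditions map with the
forest map, plus altitude-band area accounting.

The final cloud-forest map keeps only cells where both cloud-forest
*conditions* and actual forest occur; the ``removed`` layer records
conditions-but-no-forest cells.  Nodata in either input propagates —
a masked cell is unknown, never "absent".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["BinaryMapSet", "intersect_maps", "area_summary"]


@dataclass
class BinaryMapSet:
    mcf_conditions: RasterGrid
    forest: RasterGrid
    final_mcf: RasterGrid
    removed: RasterGrid  # conditions but no forest

    def cell_counts(self) -> dict[str, int]:
        def count(grid: RasterGrid) -> int:
            return int(np.nansum(np.asarray(grid.data, dtype=float) > 0))

        return {
            "mcf_conditions": count(self.mcf_conditions),
            "forest": count(self.forest),
            "final_mcf": count(self.final_mcf),
            "removed": count(self.removed),
        }

    def areas_km2(self) -> dict[str, float]:
        cell_km2 = (self.final_mcf.cell_size / 1000.0) ** 2
        return {k: v * cell_km2 for k, v in self.cell_counts().items()}


def _binary_float(grid: RasterGrid) -> np.ndarray:
    data = np.asarray(grid.data, dtype=float)
    data = np.where(grid.valid_mask, data, np.nan)
    defined = ~np.isnan(data)
    if not np.isin(data[defined], (0.0, 1.0)).all():
        raise ValueError("map is not binary 0/1")
    return data


def intersect_maps(conditions: RasterGrid, forest: RasterGrid) -> BinaryMapSet:
    """Cell-wise AND of the two binary maps, with nodata propagation."""
    conditions.require_aligned(forest)
    c = _binary_float(conditions)
    f = _binary_float(forest)
    nodata = np.isnan(c) | np.isnan(f)
    final = np.where(nodata, np.nan, ((c > 0) & (f > 0)).astype(float))
    removed = np.where(nodata, np.nan, ((c > 0) & ~(f > 0)).astype(float))
    return BinaryMapSet(
        mcf_conditions=conditions.with_data(np.where(np.isnan(c), np.nan, c)),
        forest=forest.with_data(np.where(np.isnan(f), np.nan, f)),
        final_mcf=conditions.with_data(final),
        removed=conditions.with_data(removed),
    )


def area_summary(mapset: BinaryMapSet, dem: RasterGrid, edges) -> pd.DataFrame:
    """Cell counts and areas per altitude band for each map category."""
    edges = [float(e) for e in edges]
    if sorted(edges) != edges:
        raise ValueError("altitude edges must be ascending")
    dem.require_aligned(mapset.final_mcf)
    alt = np.asarray(dem.data, dtype=float)
    final = np.asarray(mapset.final_mcf.data, dtype=float)
    removed = np.asarray(mapset.removed.data, dtype=float)
    forest = np.asarray(mapset.forest.data, dtype=float)
    cond = np.asarray(mapset.mcf_conditions.data, dtype=float)
    cell_km2 = (dem.cell_size / 1000.0) ** 2
    bounds = [-np.inf, *edges, np.inf]
    rows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (alt >= lo) & (alt < hi)
        n_final = int(np.nansum(final[sel]))
        n_removed = int(np.nansum(removed[sel]))
        n_forest_only = int(np.nansum(((forest > 0) & ~(cond > 0))[sel & ~np.isnan(forest) & ~np.isnan(cond)]))
        rows.append(
            {
                "lower_m": lo,
                "upper_m": hi,
                "final_mcf_cells": n_final,
                "final_mcf_km2": n_final * cell_km2,
                "conditions_only_cells": n_removed,
                "conditions_only_km2": n_removed * cell_km2,
                "forest_only_cells": n_forest_only,
                "forest_only_km2": n_forest_only * cell_km2,
            }
        )
    return pd.DataFrame(rows)
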