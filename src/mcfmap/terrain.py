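"""DEM-derived predictor rasters.

The quantitative terrain descriptors used as stand-ins for an ordinal
ridge/slope/valley topography classification:

* slope (degrees, Horn 3x3 kernel),
* sky view factor (horizon scan, fraction of visible sky hemisphere),
* aspect classes (k-means on the (sin, cos) embedding of aspect),
* connected entities of equal aspect class, and per entity
* vertical distance to the ridge (entity maximum) and to the valley
  bottom (entity minimum).

Everything is computed at the fine DEM resolution and block-aggregated
to the coarse analysis grid afterwards with :func:`aggregate_to_coarse`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "TerrainFeatures",
    "compute_slope",
    "compute_aspect",
    "compute_sky_view_factor",
    "classify_aspect",
    "label_entities",
    "distance_to_ridge",
    "distance_to_valley",
    "aggregate_to_coarse",
    "compute_terrain_features",
]

logger = logging.getLogger(__name__)

FLAT_CLASS = 0  # aspect class of cells with slope below the flat tolerance


def _horn_gradient(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 gradient (dz/dx eastward, dz/dy northward).

    The DEM is edge-replicated so border cells get a defined gradient;
    cells adjacent to nodata come out NaN.
    """
    z = np.asarray(dem.data, dtype=float)
    zp = np.pad(z, 1, mode="edge")
    c = dem.cell_size
    nw, n, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w, e = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * c)
    # row 0 is north, so "up" in array index is +y
    dzdy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / (8 * c)
    # the kernel omits the center cell; a nodata cell is still nodata
    center_nan = np.isnan(z)
    dzdx[center_nan] = np.nan
    dzdy[center_nan] = np.nan
    return dzdx, dzdy


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Terrain steepness in degrees from the Horn 3x3 kernel."""
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3")
    dzdx, dzdy = _horn_gradient(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.with_data(slope)


def compute_aspect(dem: RasterGrid) -> RasterGrid:
    """Azimuth of steepest descent, degrees clockwise from north."""
    dzdx, dzdy = _horn_gradient(dem)
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    return dem.with_data(aspect)


def compute_sky_view_factor(
    dem: RasterGrid, n_directions: int = 16, max_radius_m: float = 5000.0
) -> RasterGrid:
    """Fraction of the sky hemisphere visible from each cell.

    For each of ``n_directions`` azimuths the maximum horizon angle
    ``theta`` within ``max_radius_m`` is found by scanning outward
    (nearest-cell sampling, true Euclidean distances), and
    ``SVF = mean_az(1 - sin^2 theta)``; 1.0 on an open plain, low in
    pits and valleys.
    """
    if n_directions < 4:
        raise ValueError("need at least 4 azimuth directions")
    if max_radius_m < dem.cell_size:
        raise ValueError("max_radius_m must cover at least one cell")
    z = np.asarray(dem.data, dtype=float)
    nr, nc = z.shape
    n_steps = int(max_radius_m // dem.cell_size)
    svf = np.zeros_like(z)
    for az in np.arange(n_directions) * (360.0 / n_directions):
        dx = np.sin(np.radians(az))
        dy = np.cos(np.radians(az))
        seen: set[tuple[int, int]] = set()
        max_tan = np.zeros_like(z)  # horizon below eye level contributes 0
        for t in range(1, n_steps + 1):
            dc = round(t * dx)
            dr = -round(t * dy)  # +y (north) is decreasing row index
            if (dr, dc) in seen or (dr == 0 and dc == 0):
                continue
            seen.add((dr, dc))
            dist = np.hypot(dr, dc) * dem.cell_size
            if dist > max_radius_m:
                break
            if abs(dr) >= nr or abs(dc) >= nc:
                continue  # shift leaves the grid entirely
            shifted = np.full_like(z, np.nan)
            src_r = slice(max(dr, 0), nr + min(dr, 0))
            src_c = slice(max(dc, 0), nc + min(dc, 0))
            dst_r = slice(max(-dr, 0), nr + min(-dr, 0))
            dst_c = slice(max(-dc, 0), nc + min(-dc, 0))
            shifted[dst_r, dst_c] = z[src_r, src_c]
            with np.errstate(invalid="ignore"):
                tan = (shifted - z) / dist
                np.fmax(max_tan, tan, out=max_tan)
        theta = np.arctan(max_tan)
        svf += 1.0 - np.sin(theta) ** 2
    svf /= n_directions
    svf[np.isnan(z)] = np.nan
    return dem.with_data(svf)


def classify_aspect(
    dem: RasterGrid, k: int = 4, seed: int = 0, flat_tolerance_deg: float = 1.0
) -> RasterGrid:
    """Partition terrain into ``k`` aspect classes by k-means.

    Aspect is embedded as (sin a, cos a) before clustering so that
    north-facing cells are not split across the 0/360 wrap.  Cells
    flatter than ``flat_tolerance_deg`` get the dedicated FLAT class 0;
    cluster labels 1..k are renumbered by ascending circular mean
    aspect, making the output seed-deterministic and label-canonical.
    """
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    slope = compute_slope(dem).data
    aspect = compute_aspect(dem).data
    valid = ~np.isnan(slope)
    steep = valid & (slope >= flat_tolerance_deg)
    out = np.full(dem.shape, -1, dtype=np.int32)
    out[valid & ~steep] = FLAT_CLASS
    if not steep.any():
        logger.warning("all-flat DEM: every cell assigned the FLAT class")
        return dem.with_data(out, nodata=-1)
    a = np.radians(aspect[steep])
    xy = np.column_stack([np.sin(a), np.cos(a)])
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-means convergence chatter on tiny inputs
        raw = km.fit_predict(xy)
    # canonical renumbering: ascending circular mean aspect of each cluster
    centers = km.cluster_centers_
    mean_az = np.degrees(np.arctan2(centers[:, 0], centers[:, 1])) % 360.0
    order = np.argsort(mean_az, kind="stable")
    relabel = np.empty(k, dtype=np.int32)
    relabel[order] = np.arange(1, k + 1)
    out[steep] = relabel[raw]
    return dem.with_data(out, nodata=-1)


def label_entities(aspect_class: RasterGrid, connectivity: int = 8) -> RasterGrid:
    """Connected components of equal aspect class (FLAT included).

    Labels are dense positive integers; nodata cells get 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    classes = np.asarray(aspect_class.data)
    valid = aspect_class.valid_mask
    out = np.zeros(classes.shape, dtype=np.int32)
    next_label = 1
    for value in np.unique(classes[valid]):
        labeled, n = ndimage.label((classes == value) & valid, structure=structure)
        out[labeled > 0] = labeled[labeled > 0] + (next_label - 1)
        next_label += n
    return aspect_class.with_data(out, nodata=0)


def _entity_extreme(dem: RasterGrid, entity_id: RasterGrid, kind: str) -> np.ndarray:
    dem.require_aligned(entity_id)
    z = np.asarray(dem.data, dtype=float)
    ids = np.asarray(entity_id.data)
    valid = entity_id.valid_mask & ~np.isnan(z)
    n = int(ids[valid].max()) if valid.any() else 0
    fill = -np.inf if kind == "max" else np.inf
    extreme = np.full(n + 1, fill)
    op = np.maximum if kind == "max" else np.minimum
    op.at(extreme, ids[valid], z[valid])
    out = np.full(z.shape, np.nan)
    out[valid] = extreme[ids[valid]]
    out[~np.isfinite(out)] = np.nan
    return out


def distance_to_ridge(dem: RasterGrid, entity_id: RasterGrid) -> RasterGrid:
    """Vertical distance (m) to the highest cell of the cell's entity."""
    return dem.with_data(_entity_extreme(dem, entity_id, "max") - np.asarray(dem.data, float))


def distance_to_valley(dem: RasterGrid, entity_id: RasterGrid) -> RasterGrid:
    """Vertical distance (m) to the lowest cell of the cell's entity."""
    return dem.with_data(np.asarray(dem.data, float) - _entity_extreme(dem, entity_id, "min"))


def aggregate_to_coarse(fine: RasterGrid, factor: int, statistic: str = "mean") -> RasterGrid:
    """Block-aggregate a fine grid by an integer factor.

    ``mean`` for continuous rasters, ``mode`` (ties to the smallest
    value) for categorical ones.  A block at least half nodata becomes
    nodata; shapes must divide exactly — no implicit cropping.
    """
    nr, nc = fine.shape
    if factor < 1 or nr % factor or nc % factor:
        raise ValueError(f"grid shape {fine.shape} not divisible by factor {factor}")
    valid = fine.valid_mask
    blocks_valid = valid.reshape(nr // factor, factor, nc // factor, factor)
    n_valid = blocks_valid.sum(axis=(1, 3))
    half = factor * factor / 2.0
    coarse_nodata_mask = (factor * factor - n_valid) >= half

    if statistic == "mean":
        vals = np.where(valid, np.asarray(fine.data, dtype=float), 0.0)
        sums = vals.reshape(nr // factor, factor, nc // factor, factor).sum(axis=(1, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sums / n_valid
        out[coarse_nodata_mask | (n_valid == 0)] = np.nan
        nodata = None
    elif statistic == "mode":
        data = np.asarray(fine.data)
        out = np.full((nr // factor, nc // factor), -1, dtype=np.int64)
        best = np.zeros(out.shape, dtype=np.int64)
        for value in np.unique(data[valid]):
            hits = ((data == value) & valid).reshape(
                nr // factor, factor, nc // factor, factor
            ).sum(axis=(1, 3))
            take = hits > best  # ties keep the earlier (smaller) value
            out[take] = value
            best[take] = hits[take]
        out[coarse_nodata_mask | (best == 0)] = -1
        nodata = -1
    else:
        raise ValueError("statistic must be 'mean' or 'mode'")
    return RasterGrid(
        data=out,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        nodata=nodata,
    )


@dataclass
class TerrainFeatures:
    slope_deg: RasterGrid
    sky_view_factor: RasterGrid
    aspect_class: RasterGrid
    entity_id: RasterGrid
    dist_to_ridge_m: RasterGrid
    dist_to_valley_m: RasterGrid


def compute_terrain_features(
    dem: RasterGrid,
    k: int = 4,
    seed: int = 0,
    connectivity: int = 8,
    svf_directions: int = 16,
    svf_radius_m: float = 5000.0,
) -> TerrainFeatures:
    """All fine-resolution terrain predictors in one pass."""
    slope = compute_slope(dem)
    svf = compute_sky_view_factor(dem, svf_directions, svf_radius_m)
    aspect_class = classify_aspect(dem, k=k, seed=seed)
    entities = label_entities(aspect_class, connectivity=connectivity)
    return TerrainFeatures(
        slope_deg=slope,
        sky_view_factor=svf,
        aspect_class=aspect_class,
        entity_id=entities,
        dist_to_ridge_m=distance_to_ridge(dem, entities),
        dist_to_valley_m=distance_to_valley(dem, entities),
    )
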