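"""Moving-window geostatistical texture measures for raster bands.

For a window centered on each cell, pixel pairs separated by exactly
``lag`` cells along the grid axes are pooled omnidirectionally and one
of five classical structure functions is evaluated:

* variogram            gamma(h)  = sum (z(x) - z(x+h))^2 / (2N)
* madogram                        sum |z(x) - z(x+h)|    / (2N)
* rodogram                        sum |z(x) - z(x+h)|^0.5 / (2N)
* cross-variogram                 sum (za(x)-za(x+h)) (zb(x)-zb(x+h)) / (2N)
* pseudo cross-variogram          sum (za(x) - zb(x+h))^2 / (2N)

Pair-set convention (documented because several dialects exist): pairs
are axis-aligned at exact lag ``h``; for the symmetric measures each
unordered pair inside the window is counted once (N = number of such
pairs), while the pseudo cross-variogram uses ordered pairs in all four
cardinal directions, which makes it symmetric in the two bands by
construction.  Windows are truncated at the raster edge — no padding —
and pairs touching a nodata cell are dropped; centers with fewer than
``min_pairs`` valid pairs are nodata.

All window sums are computed with integral images, so the cost is
independent of the window size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .raster import RasterGrid

__all__ = ["TextureConfig", "texture_raster", "texture_suite", "MEASURES"]

SINGLE_BAND_MEASURES = ("variogram", "madogram", "rodogram")
CROSS_MEASURES = ("cross_variogram", "pseudo_cross_variogram")
MEASURES = SINGLE_BAND_MEASURES + CROSS_MEASURES


@dataclass
class TextureConfig:
    window: int = 7
    lags: tuple[int, ...] = (1, 2)
    measures: tuple[str, ...] = MEASURES
    band_pairs: list[tuple[str, str]] | None = None  # None: all unordered pairs
    min_pairs: int = 8

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if any(lag < 1 for lag in self.lags):
            raise ValueError("lags must be >= 1")
        if self.window <= 2 * max(self.lags):
            raise ValueError("window must exceed twice the largest lag")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown texture measures: {sorted(unknown)}")


def _integral_box_sum(arr, row_off, col_off, out_shape):
    """Sum of ``arr`` over the box ``[i+row_off[0], i+row_off[1]]`` x
    ``[j+col_off[0], j+col_off[1]]`` (inclusive, clipped at edges) for
    every center ``(i, j)`` in ``out_shape``."""
    nr, nc = arr.shape
    s = np.zeros((nr + 1, nc + 1))
    np.cumsum(arr, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    r0 = np.clip(np.arange(out_shape[0]) + row_off[0], 0, nr)
    r1 = np.clip(np.arange(out_shape[0]) + row_off[1] + 1, 0, nr)
    c0 = np.clip(np.arange(out_shape[1]) + col_off[0], 0, nc)
    c1 = np.clip(np.arange(out_shape[1]) + col_off[1] + 1, 0, nc)
    return (
        s[r1[:, None], c1[None, :]]
        - s[r0[:, None], c1[None, :]]
        - s[r1[:, None], c0[None, :]]
        + s[r0[:, None], c0[None, :]]
    )


def _pair_kernel(measure: str, da: np.ndarray, db: np.ndarray | None) -> np.ndarray:
    if measure == "variogram":
        return da * da
    if measure == "madogram":
        return np.abs(da)
    if measure == "rodogram":
        return np.sqrt(np.abs(da))
    if measure == "cross_variogram":
        return da * db
    raise AssertionError(measure)


def texture_raster(
    band_a: RasterGrid,
    band_b: RasterGrid | None,
    measure: str,
    lag: int,
    window: int,
    min_pairs: int = 8,
) -> RasterGrid:
    """One texture measure at one lag, evaluated at every cell."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    is_cross = measure in CROSS_MEASURES
    if is_cross and band_b is None:
        raise ValueError(f"{measure} requires a second band")
    if not is_cross and band_b is not None:
        raise ValueError(f"{measure} is a single-band measure")
    if lag >= window:
        raise ValueError(f"lag {lag} must be smaller than window {window}")
    if window % 2 == 0:
        raise ValueError("window must be odd")

    a = np.asarray(band_a.data, dtype=float)
    va = band_a.valid_mask
    if band_b is not None:
        band_a.require_aligned(band_b)
        b = np.asarray(band_b.data, dtype=float)
        vb = band_b.valid_mask
    else:
        b, vb = a, va

    k = window // 2
    shape = a.shape
    total = np.zeros(shape)
    count = np.zeros(shape)

    def accumulate(term, valid, row_off, col_off):
        term = np.where(valid, np.nan_to_num(term), 0.0)
        total_part = _integral_box_sum(term, row_off, col_off, shape)
        count_part = _integral_box_sum(valid.astype(float), row_off, col_off, shape)
        np.add(total, total_part, out=total)
        np.add(count, count_part, out=count)

    if measure == "pseudo_cross_variogram":
        # ordered pairs, 4 cardinal directions; anchor at the lower-index cell
        for da_arr, valid, axis in (
            ((a[:, :-lag] - b[:, lag:]) ** 2, va[:, :-lag] & vb[:, lag:], 1),
            ((a[:, lag:] - b[:, :-lag]) ** 2, va[:, lag:] & vb[:, :-lag], 1),
            ((a[:-lag, :] - b[lag:, :]) ** 2, va[:-lag, :] & vb[lag:, :], 0),
            ((a[lag:, :] - b[:-lag, :]) ** 2, va[lag:, :] & vb[:-lag, :], 0),
        ):
            if axis == 1:
                accumulate(da_arr, valid, (-k, k), (-k, k - lag))
            else:
                accumulate(da_arr, valid, (-k, k - lag), (-k, k))
    else:
        # unordered pairs, horizontal + vertical, anchored at the left/top cell
        da_h = a[:, :-lag] - a[:, lag:]
        db_h = b[:, :-lag] - b[:, lag:]
        accumulate(
            _pair_kernel(measure, da_h, db_h),
            va[:, :-lag] & va[:, lag:] & vb[:, :-lag] & vb[:, lag:],
            (-k, k),
            (-k, k - lag),
        )
        da_v = a[:-lag, :] - a[lag:, :]
        db_v = b[:-lag, :] - b[lag:, :]
        accumulate(
            _pair_kernel(measure, da_v, db_v),
            va[:-lag, :] & va[lag:, :] & vb[:-lag, :] & vb[lag:, :],
            (-k, k - lag),
            (-k, k),
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / (2.0 * count)
    out[count < min_pairs] = np.nan
    return band_a.with_data(out)


def feature_name(measure: str, bands: str | tuple[str, str], lag: int) -> str:
    tag = bands if isinstance(bands, str) else "".join(bands)
    return f"tex_{measure}_{tag}_lag{lag}"


def texture_suite(
    bands: dict[str, RasterGrid], config: TextureConfig | None = None
) -> dict[str, RasterGrid]:
    """All configured measures for all bands / unordered band pairs and lags.

    Feature names follow ``tex_<measure>_<bands>_lag<h>`` and are unique.
    The pseudo cross-variogram is already order-symmetric under the
    4-direction pair convention, so each unordered pair is computed once.
    """
    config = config or TextureConfig()
    names = list(bands)
    pairs = config.band_pairs
    if pairs is None:
        pairs = list(combinations(names, 2))
    out: dict[str, RasterGrid] = {}
    for lag in config.lags:
        for m in config.measures:
            if m in SINGLE_BAND_MEASURES:
                for name in names:
                    out[feature_name(m, name, lag)] = texture_raster(
                        bands[name], None, m, lag, config.window, config.min_pairs
                    )
            else:
                for na, nb in pairs:
                    out[feature_name(m, (na, nb), lag)] = texture_raster(
                        bands[na], bands[nb], m, lag, config.window, config.min_pairs
                    )
    return out
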