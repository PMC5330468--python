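"""Synthetic study area generator.

Builds a fully self-contained stand-in for the real inputs of a
montane-cloud-forest mapping study: a multi-massif DEM, monthly
ground-fog probability fields, a stack of per-scene fog/clear/invalid
observation masks, class-dependent 6-band reflectance mosaics, and
labelled vegetation / forest point records.

The generated world reproduces, by construction, the qualitative
structure the downstream analysis depends on:

* fog probability is a bell-shaped function of altitude, peaking in the
  montane belt;
* in winter-monsoon months the bell center is lowered on slopes facing
  the windward azimuth and on isolated massifs (a Massenerhebung
  analog), producing a low-altitude fog fringe; summer months are
  flatter and weaker;
* cloud-forest conditions hold where annual fog probability exceeds a
  threshold within an altitude corridor, giving a clean upper boundary
  driven by altitude and a lower fringe driven only by fog;
* band spectra differ subtly between cloud forest, other forest and
  non-forest, with class-specific spatial correlation lengths so that
  texture measures carry class signal.

Every stochastic stage draws from ``default_rng([seed, stage])``, so a
fixed config + seed yields bit-identical output regardless of which
stages are run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .climatology import CLEAR, FOG, INVALID, FogMaskSeries
from .raster import RasterGrid
from .terrain import aggregate_to_coarse, compute_aspect, compute_slope

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "Massif",
    "FogParams",
    "McfRule",
    "BandSpectra",
    "LandscapeConfig",
    "SyntheticTruth",
    "SyntheticWorld",
    "generate_dem",
    "windwardness",
    "isolation_score",
    "generate_fog_probability",
    "simulate_fog_masks",
    "generate_labels_and_plots",
    "generate_reflectance",
    "generate_world",
]

BAND_NAMES = ("b1", "b2", "b3", "b4", "b5", "b7")

# rng stream ids, one per stochastic stage
_STAGE_MASKS, _STAGE_PLOTS, _STAGE_BANDS, _STAGE_FOREST_PTS = 1, 2, 3, 4


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


class SimulationError(RuntimeError):
    """Configuration is valid but produces a degenerate world."""


@dataclass
class Massif:
    center_xy: tuple[float, float]  # meters in the local grid frame
    height_m: float
    radius_m: float  # Gaussian sigma of the hill


@dataclass
class FogParams:
    """Parameters of the closed-form monthly fog-probability law.

    Winter months (the monsoon season): probability is
    ``base_rate + peak_winter * exp(-(alt - c)^2 / (2 width_winter^2))``
    with the bell center
    ``c = center_altitude - windward_lowering * w - isolation_lowering * iso``,
    where ``w`` in [0, 1] is the windwardness of the cell (cosine of the
    aspect/monsoon-azimuth difference, scaled by slope) and ``iso`` in
    [0, 1] the massif-isolation score.  Summer months use the fixed
    center with a wider, weaker bell.
    """

    center_altitude_m: float = 2000.0
    width_winter_m: float = 500.0
    width_summer_m: float = 800.0
    peak_winter: float = 0.6
    peak_summer: float = 0.3
    base_rate: float = 0.02
    windward_lowering_m: float = 600.0
    isolation_lowering_m: float = 500.0
    winter_months: tuple[int, ...] = (9, 10, 11, 12, 1, 2, 3, 4)
    slope_saturation_deg: float = 10.0
    isolation_radius_m: float = 3000.0
    isolation_norm_m: float = 1500.0


@dataclass
class McfRule:
    """Label rule: MCF conditions where annual fog probability is at
    least ``fog_threshold`` and altitude lies in [floor, ceiling]."""

    fog_threshold: float = 0.25
    floor_m: float = 800.0
    ceiling_m: float = 2600.0
    treeline_m: float = 3100.0
    # axis-aligned cleared rectangles (x_min, x_max, y_min, y_max), meters
    cleared_rects: list[tuple[float, float, float, float]] = field(default_factory=list)


@dataclass
class BandSpectra:
    """Mean reflectance per class and band, with class-specific noise
    correlation lengths (in fine cells).

    Cloud forest is spectrally close to other evergreen forest —
    slightly lower NIR/SWIR from moister, shorter canopies — while
    non-forest is distinct; the decisive class information is meant to
    come from fog climatology, not spectra.
    """

    means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "non_forest": (0.10, 0.12, 0.14, 0.25, 0.28, 0.22),
            "forest": (0.03, 0.05, 0.04, 0.30, 0.14, 0.06),
            "mcf": (0.03, 0.05, 0.04, 0.27, 0.12, 0.05),
        }
    )
    sd: float = 0.05
    correlation_length_cells: dict[str, float] = field(
        default_factory=lambda: {"non_forest": 2.0, "forest": 6.0, "mcf": 4.0}
    )


@dataclass
class LandscapeConfig:
    grid_rows: int = 400
    grid_cols: int = 400
    cell_size_m: float = 30.0
    coarse_factor: int = 8
    n_scenes: int = 300
    month_shares: tuple[float, ...] = (1 / 12,) * 12
    invalid_fraction: float = 0.3
    seed: int = 0
    relief: list[Massif] = field(
        default_factory=lambda: [
            Massif((6000.0, 5000.0), 3100.0, 2600.0),  # main range, south-center
            Massif((4600.0, 8200.0), 2700.0, 2000.0),  # main range, north
            Massif((9800.0, 3400.0), 1500.0, 900.0),   # isolated coastal massif
            Massif((2400.0, 10600.0), 1000.0, 700.0),  # isolated northern massif
        ]
    )
    base_min_m: float = 0.0
    base_max_m: float = 150.0
    windward_azimuth_deg: float = 45.0  # NE winter monsoon analog
    fog_params: FogParams = field(default_factory=FogParams)
    # default clearing: an urbanized patch on the low seaward flank of
    # the isolated northern massif, where condition cells lose forest
    mcf_rule: McfRule = field(
        default_factory=lambda: McfRule(
            cleared_rects=[(1600.0, 3200.0, 9800.0, 11400.0)]
        )
    )
    band_spectra: BandSpectra = field(default_factory=BandSpectra)
    n_plots: int = 600
    mcf_plot_fraction: float = 0.35  # mirrors the 35/65 class balance of real plots
    n_altitude_strata: int = 10
    min_plots_per_stratum: int = 5
    n_forest_points: int = 400
    forest_point_fraction: float = 0.55

    def __post_init__(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if self.grid_rows % self.coarse_factor or self.grid_cols % self.coarse_factor:
            raise ConfigurationError("grid dimensions must divide by coarse_factor")
        if not 0 <= self.invalid_fraction < 1:
            raise ConfigurationError("invalid_fraction must be in [0, 1)")
        shares = np.asarray(self.month_shares, dtype=float)
        if shares.shape != (12,) or (shares < 0).any() or shares.sum() <= 0:
            raise ConfigurationError("month_shares must be 12 non-negative weights")
        fp = self.fog_params
        if not (0 <= fp.base_rate + fp.peak_winter <= 1 and 0 <= fp.base_rate + fp.peak_summer <= 1):
            raise ConfigurationError("fog probabilities must stay within [0, 1]")

    @property
    def extent_m(self) -> tuple[float, float]:
        return self.grid_cols * self.cell_size_m, self.grid_rows * self.cell_size_m

    def normalized_month_shares(self) -> np.ndarray:
        shares = np.asarray(self.month_shares, dtype=float)
        return shares / shares.sum()

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "LandscapeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["relief"] = [Massif(tuple(m["center_xy"]), m["height_m"], m["radius_m"])
                         for m in raw.get("relief", [])]
        for key, sub in (("fog_params", FogParams), ("mcf_rule", McfRule),
                         ("band_spectra", BandSpectra)):
            if key in raw:
                raw[key] = sub(**raw[key])
        if "mcf_rule" in raw and raw["mcf_rule"].cleared_rects:
            raw["mcf_rule"].cleared_rects = [tuple(r) for r in raw["mcf_rule"].cleared_rects]
        raw["month_shares"] = tuple(raw.get("month_shares", (1 / 12,) * 12))
        return cls(**raw)


@dataclass
class SyntheticTruth:
    dem: RasterGrid
    fog_prob_monthly: list[RasterGrid]
    annual_fog_prob: RasterGrid
    mcf_truth: RasterGrid  # 1 where MCF conditions hold (forested or not)
    forest_truth: RasterGrid
    plots: pd.DataFrame
    forest_points: pd.DataFrame


@dataclass
class SyntheticWorld:
    truth: SyntheticTruth
    masks: FogMaskSeries  # simulated scenes at the coarse analysis grid
    bands: dict[str, RasterGrid]  # fine-grid reflectance mosaics
    config: LandscapeConfig


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------

def _cell_centers(config: LandscapeConfig) -> tuple[np.ndarray, np.ndarray]:
    width, height = config.extent_m
    x = (np.arange(config.grid_cols) + 0.5) * config.cell_size_m
    y = height - (np.arange(config.grid_rows) + 0.5) * config.cell_size_m
    return np.meshgrid(x, y)


def generate_dem(config: LandscapeConfig) -> RasterGrid:
    """Sum-of-Gaussian-hills terrain over a gentle west-east base ramp.

    Closed form (used verbatim by the test oracle):
    ``z(x, y) = base_min + (base_max - base_min) * x / width
    + sum_i h_i * exp(-((x-cx_i)^2 + (y-cy_i)^2) / (2 r_i^2))``.
    """
    if not config.relief:
        raise ConfigurationError("at least one massif descriptor required")
    for m in config.relief:
        if m.height_m <= 0 or m.radius_m <= 0:
            raise ConfigurationError(f"non-positive massif height/radius: {m}")
    xx, yy = _cell_centers(config)
    width, height = config.extent_m
    z = config.base_min_m + (config.base_max_m - config.base_min_m) * xx / width
    for m in config.relief:
        cx, cy = m.center_xy
        z = z + m.height_m * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * m.radius_m**2))
    return RasterGrid(data=z, cell_size=config.cell_size_m, origin=(0.0, height))


def windwardness(dem: RasterGrid, azimuth_deg: float, slope_saturation_deg: float = 10.0) -> np.ndarray:
    """Exposure of each cell to flow from ``azimuth_deg``, in [0, 1].

    ``max(0, cos(aspect - azimuth)) * min(1, slope / slope_saturation)``:
    full weight on steep slopes facing the flow, zero on lee slopes and
    plains.
    """
    aspect = compute_aspect(dem).data
    slope = compute_slope(dem).data
    cosine = np.cos(np.radians(aspect - azimuth_deg))
    return np.clip(cosine, 0.0, None) * np.clip(slope / slope_saturation_deg, 0.0, 1.0)


def isolation_score(
    dem: RasterGrid, radius_m: float = 3000.0, norm_m: float = 1500.0
) -> np.ndarray:
    """Massif-isolation score in [0, 1]: local altitude minus the mean
    altitude in an annulus [radius/3, radius], scaled by ``norm_m``.

    High on small mountains surrounded by lowland, low inside a large
    massif — a minimal monotone Massenerhebung proxy.
    """
    z = np.asarray(dem.data, dtype=float)
    n = int(radius_m // dem.cell_size)
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    dist = np.hypot(yy, xx) * dem.cell_size
    kernel = ((dist <= radius_m) & (dist >= radius_m / 3.0)).astype(float)
    kernel /= kernel.sum()
    ring_mean = fftconvolve(z, kernel, mode="same")
    coverage = fftconvolve(np.ones_like(z), kernel, mode="same")
    ring_mean = ring_mean / coverage  # renormalize truncated edge kernels
    return np.clip((z - ring_mean) / norm_m, 0.0, 1.0)


# ---------------------------------------------------------------------------
# fog
# ---------------------------------------------------------------------------

def generate_fog_probability(dem: RasterGrid, config: LandscapeConfig) -> list[RasterGrid]:
    """12 monthly ground-fog probability grids from the closed-form law
    documented on :class:`FogParams`."""
    fp = config.fog_params
    alt = np.asarray(dem.data, dtype=float)
    if not np.isfinite(alt).all():
        raise ConfigurationError("DEM must be finite")
    w = windwardness(dem, config.windward_azimuth_deg, fp.slope_saturation_deg)
    iso = isolation_score(dem, fp.isolation_radius_m, fp.isolation_norm_m)
    grids: list[RasterGrid] = []
    for month in range(1, 13):
        if month in fp.winter_months:
            center = (
                fp.center_altitude_m
                - fp.windward_lowering_m * w
                - fp.isolation_lowering_m * iso
            )
            p = fp.base_rate + fp.peak_winter * np.exp(
                -((alt - center) ** 2) / (2 * fp.width_winter_m**2)
            )
        else:
            p = fp.base_rate + fp.peak_summer * np.exp(
                -((alt - fp.center_altitude_m) ** 2) / (2 * fp.width_summer_m**2)
            )
        grids.append(dem.with_data(np.clip(p, 0.0, 1.0)))
    return grids


def annual_probability(fog_prob: list[RasterGrid], config: LandscapeConfig) -> RasterGrid:
    """Scene-share-weighted annual fog probability."""
    shares = config.normalized_month_shares()
    acc = sum(s * np.asarray(g.data, float) for s, g in zip(shares, fog_prob))
    return fog_prob[0].with_data(acc)


def simulate_fog_masks(
    fog_prob: list[RasterGrid], config: LandscapeConfig, n_scenes: int | None = None
) -> FogMaskSeries:
    """Draw per-scene {FOG, CLEAR, INVALID} grids from monthly probabilities.

    Scene counts per month follow ``month_shares`` (largest-remainder
    rounding); each scene is an independent cell-wise Bernoulli draw
    from its month's probability, overlaid with independent invalid
    retrievals at ``invalid_fraction``.
    """
    n = config.n_scenes if n_scenes is None else n_scenes
    if n < 1:
        raise ConfigurationError("n_scenes must be >= 1")
    shares = config.normalized_month_shares()
    counts = np.floor(shares * n).astype(int)
    remainder = shares * n - counts
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1

    rng = np.random.default_rng([config.seed, _STAGE_MASKS])
    shape = fog_prob[0].shape
    codes = np.empty((n, *shape), dtype=np.uint8)
    months = np.empty(n, dtype=int)
    scene = 0
    for month in range(1, 13):
        p = np.asarray(fog_prob[month - 1].data, dtype=float)
        for _ in range(counts[month - 1]):
            obs = (rng.random(shape) < p).astype(np.uint8)  # FOG=1, CLEAR=0
            if config.invalid_fraction > 0:
                obs[rng.random(shape) < config.invalid_fraction] = INVALID
            codes[scene] = obs
            months[scene] = month
            scene += 1
    return FogMaskSeries(
        codes=codes, months=months,
        cell_size=fog_prob[0].cell_size, origin=fog_prob[0].origin,
    )


# ---------------------------------------------------------------------------
# labels and points
# ---------------------------------------------------------------------------

def _cleared_mask(config: LandscapeConfig, dem: RasterGrid) -> np.ndarray:
    xx, yy = _cell_centers(config)
    mask = np.zeros(dem.shape, dtype=bool)
    for x0, x1, y0, y1 in config.mcf_rule.cleared_rects:
        mask |= (xx >= x0) & (xx < x1) & (yy >= y0) & (yy < y1)
    return mask


def _stratified_cells(
    rng: np.random.Generator,
    candidate_rc: np.ndarray,
    altitudes: np.ndarray,
    n_target: int,
    decile_edges: np.ndarray,
    min_per_stratum: int,
) -> np.ndarray:
    """Sample candidate cell indices stratified over altitude deciles.

    Allocation is proportional to availability, with a minimum per
    non-empty stratum; deterministic under the supplied rng.
    """
    n_strata = len(decile_edges) - 1
    stratum = np.clip(np.digitize(altitudes, decile_edges[1:-1]), 0, n_strata - 1)
    avail = [np.where(stratum == s)[0] for s in range(n_strata)]
    avail_n = np.array([len(a) for a in avail])
    share = avail_n / avail_n.sum()
    alloc = np.floor(share * n_target).astype(int)
    for idx in np.argsort(-(share * n_target - alloc), kind="stable")[: n_target - alloc.sum()]:
        alloc[idx] += 1
    alloc = np.minimum(np.maximum(alloc, np.where(avail_n > 0, min_per_stratum, 0)), avail_n)
    # trim any overshoot from the largest allocations
    while alloc.sum() > n_target:
        alloc[np.argmax(alloc)] -= 1
    chosen = [rng.choice(a, size=k, replace=False) for a, k in zip(avail, alloc) if k > 0]
    return candidate_rc[np.concatenate(chosen)] if chosen else np.empty((0, 2), int)


def _points_table(dem: RasterGrid, rc: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    rows, cols = rc[:, 0], rc[:, 1]
    xy = np.array([dem.xy_of(int(r), int(c)) for r, c in rc]) if len(rc) else np.empty((0, 2))
    return pd.DataFrame(
        {
            "id": np.arange(len(rc)),
            "row": rows,
            "col": cols,
            "x_m": xy[:, 0] if len(rc) else [],
            "y_m": xy[:, 1] if len(rc) else [],
            "altitude_m": np.asarray(dem.data, float)[rows, cols],
            "label": labels.astype(int),
        }
    )


def generate_labels_and_plots(
    dem: RasterGrid, fog_prob: list[RasterGrid], config: LandscapeConfig
) -> SyntheticTruth:
    """Truth grids plus stratified labelled point samples.

    MCF-conditions truth applies the fog-threshold/altitude-corridor
    rule to the *annual* fog probability; forest truth is everything
    below the treeline outside cleared rectangles.  Vegetation plots
    are drawn from forested cells, stratified over altitude deciles of
    the forest area, with the configured MCF / non-MCF balance; labels
    are read from the truth grids, so plot labels agree with the truth
    at their cells by construction.
    """
    rule = config.mcf_rule
    alt = np.asarray(dem.data, dtype=float)
    annual = annual_probability(fog_prob, config)
    mcf = (
        (np.asarray(annual.data) >= rule.fog_threshold)
        & (alt >= rule.floor_m)
        & (alt <= rule.ceiling_m)
    )
    forest = (alt < rule.treeline_m) & ~_cleared_mask(config, dem)

    mcf_forest = mcf & forest
    nonmcf_forest = forest & ~mcf
    if not forest.any():
        raise SimulationError("treeline/clearing rule produced no forest at all")
    if not mcf_forest.any():
        raise SimulationError(
            "label rule produced no forested MCF cells "
            f"(fog_threshold={rule.fog_threshold}, corridor "
            f"[{rule.floor_m}, {rule.ceiling_m}] m)"
        )
    if not nonmcf_forest.any():
        # a degenerate all-MCF world is still a valid truth grid; plots
        # then come from a single class
        logging.getLogger(__name__).warning(
            "label rule covers every forested cell; plots will be single-class"
        )

    forest_alt = alt[forest]
    decile_edges = np.quantile(forest_alt, np.linspace(0, 1, config.n_altitude_strata + 1))
    decile_edges[-1] = np.inf

    rng = np.random.default_rng([config.seed, _STAGE_PLOTS])
    n_mcf = int(round(config.n_plots * config.mcf_plot_fraction))
    picks = []
    for mask, n_target in ((mcf_forest, n_mcf), (nonmcf_forest, config.n_plots - n_mcf)):
        rc = np.argwhere(mask)
        if len(rc) == 0 or n_target == 0:
            continue
        picks.append(
            _stratified_cells(
                rng, rc, alt[mask.nonzero()], n_target, decile_edges,
                config.min_plots_per_stratum,
            )
        )
    rc_all = np.concatenate(picks)
    labels = mcf[rc_all[:, 0], rc_all[:, 1]]
    plots = _points_table(dem, rc_all, labels)

    rng_fp = np.random.default_rng([config.seed, _STAGE_FOREST_PTS])
    n_forest = int(round(config.n_forest_points * config.forest_point_fraction))
    forest_rc = np.argwhere(forest)
    open_rc = np.argwhere(~forest)
    parts = []
    if len(forest_rc):
        k = min(n_forest, len(forest_rc))
        parts.append(forest_rc[rng_fp.choice(len(forest_rc), size=k, replace=False)])
    if len(open_rc):
        k = min(config.n_forest_points - n_forest, len(open_rc))
        parts.append(open_rc[rng_fp.choice(len(open_rc), size=k, replace=False)])
    rc_fp = np.concatenate(parts)
    forest_points = _points_table(dem, rc_fp, forest[rc_fp[:, 0], rc_fp[:, 1]])

    return SyntheticTruth(
        dem=dem,
        fog_prob_monthly=fog_prob,
        annual_fog_prob=annual,
        mcf_truth=dem.with_data(mcf.astype(np.int8)),
        forest_truth=dem.with_data(forest.astype(np.int8)),
        plots=plots,
        forest_points=forest_points,
    )


# ---------------------------------------------------------------------------
# reflectance
# ---------------------------------------------------------------------------

def class_map(truth: SyntheticTruth) -> np.ndarray:
    """0 = non-forest, 1 = forest (non-MCF), 2 = cloud forest."""
    forest = np.asarray(truth.forest_truth.data) > 0
    mcf = np.asarray(truth.mcf_truth.data) > 0
    out = np.zeros(forest.shape, dtype=np.int8)
    out[forest] = 1
    out[forest & mcf] = 2
    return out


def generate_reflectance(
    truth: SyntheticTruth, config: LandscapeConfig
) -> dict[str, RasterGrid]:
    """Six-band reflectance mosaics with class-dependent spectra and
    class-specific spatial correlation lengths, clipped to [0, 1]."""
    spectra = config.band_spectra
    classes = class_map(truth)
    class_names = ("non_forest", "forest", "mcf")
    rng = np.random.default_rng([config.seed, _STAGE_BANDS])
    out: dict[str, RasterGrid] = {}
    for b, band in enumerate(BAND_NAMES):
        composite = np.zeros(classes.shape)
        for ci, cname in enumerate(class_names):
            mean = spectra.means[cname][b]
            if spectra.sd > 0:
                corr = spectra.correlation_length_cells[cname]
                noise = gaussian_filter(rng.standard_normal(classes.shape), sigma=corr)
                noise /= noise.std()
                values = mean + spectra.sd * noise
            else:
                values = np.full(classes.shape, mean)
            composite[classes == ci] = values[classes == ci]
        out[band] = truth.dem.with_data(np.clip(composite, 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# one-call world builder
# ---------------------------------------------------------------------------

def generate_world(config: LandscapeConfig | None = None) -> SyntheticWorld:
    """DEM -> fog probabilities -> labels/plots -> scenes -> reflectance.

    Fog scenes are simulated on the coarse analysis grid (the native
    resolution of the satellite fog product they stand in for), from
    block-mean-aggregated monthly probabilities.
    """
    config = config or LandscapeConfig()
    dem = generate_dem(config)
    fog_prob = generate_fog_probability(dem, config)
    truth = generate_labels_and_plots(dem, fog_prob, config)
    coarse_prob = [aggregate_to_coarse(g, config.coarse_factor, "mean") for g in fog_prob]
    masks = simulate_fog_masks(coarse_prob, config)
    bands = generate_reflectance(truth, config)
    return SyntheticWorld(truth=truth, masks=masks, bands=bands, config=config)
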