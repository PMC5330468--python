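"""End-to-end pipeline over the synthetic world.

Chains the stages exactly as a real mapping campaign would: simulate
(or load) the inputs, build the fog climatology from the scene masks,
derive terrain and texture predictors at fine resolution, aggregate
everything to the coarse analysis grid, sample the predictors at plot
locations, train the condition model variants, verify out-of-bag, and
intersect the predicted conditions map with the forest map.

The two standard model variants mirror the central comparison of the
study design: variant A uses all input sets (fog + dem + landsat),
variant B excludes the fog climatology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import TrainedModel, predict_map, train
from .climatology import FogClimatology, build_climatology
from .features import FeatureMatrix, sample_at_plots, subset_by_group
from .maps import BinaryMapSet, intersect_maps
from .raster import RasterGrid
from .synthetic import BAND_NAMES, LandscapeConfig, SyntheticWorld, generate_world
from .terrain import aggregate_to_coarse, compute_terrain_features
from .texture import TextureConfig, texture_suite
from .verification import VerificationReport, stratified_report

__all__ = ["PipelineResult", "build_coarse_rasters", "assemble_features", "run_pipeline"]

# analysis-grid altitude boundary separating the fog-driven low fringe
# from the altitude-driven upper belt
LOW_STRATUM_EDGE_M = 1500.0


@dataclass
class PipelineResult:
    world: SyntheticWorld
    climatology: FogClimatology
    coarse_rasters: dict[str, RasterGrid]
    features: FeatureMatrix
    model_a: TrainedModel  # fog + dem + landsat
    model_b: TrainedModel  # dem + landsat (no fog)
    reports_a: list[VerificationReport]
    reports_b: list[VerificationReport]

    def report_frame(self) -> pd.DataFrame:
        rows = []
        for variant, reports in (("A", self.reports_a), ("B", self.reports_b)):
            for r in reports:
                d = r.as_dict()
                d["variant"] = variant
                rows.append(d)
        return pd.DataFrame(rows)


def build_coarse_rasters(
    world: SyntheticWorld,
    climatology: FogClimatology,
    texture_config: TextureConfig | None = None,
    terrain_seed: int = 0,
) -> dict[str, RasterGrid]:
    """All predictor rasters on the coarse analysis grid.

    Terrain, bands and textures are computed at the fine DEM/mosaic
    resolution and block-mean aggregated; the fog climatology is native
    to the coarse grid.
    """
    cfg = world.config
    factor = cfg.coarse_factor
    dem = world.truth.dem

    rasters: dict[str, RasterGrid] = {}
    for month, grid in enumerate(climatology.monthly_frequency, start=1):
        rasters[f"fog_f{month:02d}"] = grid
    rasters["fog_annual"] = climatology.annual_frequency

    terr = compute_terrain_features(dem, seed=terrain_seed)
    rasters["altitude"] = aggregate_to_coarse(dem, factor, "mean")
    rasters["slope"] = aggregate_to_coarse(terr.slope_deg, factor, "mean")
    rasters["sky_view_factor"] = aggregate_to_coarse(terr.sky_view_factor, factor, "mean")
    rasters["dist_to_ridge"] = aggregate_to_coarse(terr.dist_to_ridge_m, factor, "mean")
    rasters["dist_to_valley"] = aggregate_to_coarse(terr.dist_to_valley_m, factor, "mean")

    for name in BAND_NAMES:
        rasters[name] = aggregate_to_coarse(world.bands[name], factor, "mean")
    for name, grid in texture_suite(world.bands, texture_config).items():
        rasters[name] = aggregate_to_coarse(grid, factor, "mean")
    return rasters


def assemble_features(
    coarse_rasters: dict[str, RasterGrid], plots: pd.DataFrame
) -> FeatureMatrix:
    return sample_at_plots(coarse_rasters, plots)


def run_pipeline(
    config: LandscapeConfig | None = None,
    seed: int | None = None,
    n_trees: int = 500,
    texture_config: TextureConfig | None = None,
    min_valid: int = 10,
) -> PipelineResult:
    """Simulate a world and run the full analysis on it.

    ``seed`` overrides ``config.seed`` for the whole run (world
    generation and model training).
    """
    config = config or LandscapeConfig()
    if seed is not None:
        from dataclasses import replace

        config = replace(config, seed=seed)
    rf_seed = config.seed

    world = generate_world(config)
    climatology = build_climatology(world.masks, min_valid_threshold=min_valid)
    coarse = build_coarse_rasters(world, climatology, texture_config, terrain_seed=rf_seed)
    fm = assemble_features(coarse, world.truth.plots)

    model_a = train(fm, seed=rf_seed, n_trees=n_trees)
    fm_b = subset_by_group(fm, {"dem", "landsat"})
    model_b = train(fm_b, seed=rf_seed, n_trees=n_trees)

    edges = [LOW_STRATUM_EDGE_M]
    reports_a = stratified_report(
        fm.y.to_numpy(), model_a.oob_predictions, fm.altitudes.to_numpy(), edges
    )
    reports_b = stratified_report(
        fm_b.y.to_numpy(), model_b.oob_predictions, fm_b.altitudes.to_numpy(), edges
    )
    return PipelineResult(
        world=world,
        climatology=climatology,
        coarse_rasters=coarse,
        features=fm,
        model_a=model_a,
        model_b=model_b,
        reports_a=reports_a,
        reports_b=reports_b,
    )


def final_map_products(
    result: PipelineResult, forest_model: TrainedModel | None = None
) -> BinaryMapSet:
    """Predict the conditions map (variant A) and intersect it with the
    forest map.

    Without a trained forest model the coarse-aggregated forest truth
    serves as the forest map.
    """
    conditions = predict_map(result.model_a, result.coarse_rasters)
    if forest_model is not None:
        forest = predict_map(forest_model, result.coarse_rasters)
    else:
        forest_fine = result.world.truth.forest_truth
        coarse = aggregate_to_coarse(forest_fine, result.world.config.coarse_factor, "mode")
        data = np.asarray(coarse.data, dtype=float)
        data[data < 0] = np.nan
        forest = conditions.with_data(data)
    return intersect_maps(conditions, forest)
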