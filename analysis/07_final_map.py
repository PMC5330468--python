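"""Forest map and final cloud-forest map.

Trains the forest/non-forest model on its own point set using the
spectral + texture inputs, predicts both binary maps over the full
grid, intersects them, and accounts for the area removed where
cloud-forest conditions fall outside forest.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mcfmap.classification import predict_map, train
from mcfmap.features import sample_at_plots, subset_by_group
from mcfmap.maps import area_summary, intersect_maps
from mcfmap.pipeline import run_pipeline
from mcfmap.raster import write_ascii_grid
from mcfmap.verification import confusion_from_oob, statistics

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "maps"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(seed=42)

    # forest model: spectral + texture inputs sampled at the forest points
    fm_forest = subset_by_group(
        sample_at_plots(result.coarse_rasters, result.world.truth.forest_points),
        {"landsat"},
    )
    forest_model = train(fm_forest, seed=42)
    report = statistics(
        confusion_from_oob(fm_forest.y.to_numpy(), forest_model.oob_predictions)
    )
    print("forest map OOB:", report.rounded(2), report.counts)

    conditions = predict_map(result.model_a, result.coarse_rasters)
    forest = predict_map(forest_model, result.coarse_rasters)
    mapset = intersect_maps(conditions, forest)
    counts = mapset.cell_counts()
    print("cell counts:", counts)

    dem = result.coarse_rasters["altitude"]
    table = area_summary(mapset, dem, [1000, 1500, 2000, 2500])
    table.to_csv(RESULTS / "final_map_areas.csv", index=False)
    print(table.round(2).to_string(index=False))

    write_ascii_grid(mapset.final_mcf, str(SCRATCH / "final_mcf.asc"))
    write_ascii_grid(mapset.removed, str(SCRATCH / "removed.asc"))

    removed_frac = counts["removed"] / max(counts["mcf_conditions"], 1)
    print(
        f"\n{counts['final_mcf']} coarse cells of final cloud forest; "
        f"{removed_frac:.1%} of condition cells removed for lack of forest."
    )


if __name__ == "__main__":
    main()
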