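"""Assembly of the plots x features training matrix.

Every coarse predictor raster is sampled at the plot locations by
nearest cell (no interpolation — frequency and categorical rasters
must not be blended), using half-open cell intervals.  Rows touching
nodata in any feature are dropped and reported per feature, so the
matrix entering training is complete.

Each feature carries a group tag (``fog``, ``dem`` or ``landsat``) so
models can be trained on input-set subsets and ablations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = ["FeatureMatrix", "infer_group", "sample_at_plots", "subset_by_group"]

logger = logging.getLogger(__name__)

KNOWN_GROUPS = ("fog", "dem", "landsat")


def infer_group(feature_name: str) -> str:
    """Input-set tag from the feature naming convention."""
    if feature_name.startswith("fog_"):
        return "fog"
    if feature_name in ("altitude", "slope", "sky_view_factor") or feature_name.startswith("dist_to_"):
        return "dem"
    if feature_name.startswith(("b", "tex_")):
        return "landsat"
    raise KeyError(f"cannot infer feature group for {feature_name!r}")


@dataclass
class FeatureMatrix:
    X: pd.DataFrame  # rows indexed by plot id, named feature columns
    y: pd.Series  # binary labels aligned to X
    groups: dict[str, str]  # feature name -> input-set tag
    altitudes: pd.Series  # plot altitude, for stratified verification
    dropped_rows: list = field(default_factory=list)
    dropout_report: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if not set(self.y.unique()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        unknown = set(self.groups.values()) - set(KNOWN_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups {sorted(unknown)}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def to_csv(self, path: str) -> None:
        table = self.X.copy()
        table["label"] = self.y
        table["altitude_m"] = self.altitudes
        table.to_csv(path, index_label="plot_id")


def sample_at_plots(
    rasters: dict[str, RasterGrid],
    plots: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> FeatureMatrix:
    """Value of each raster at the cell containing each plot.

    ``plots`` needs columns ``id``, ``x_m``, ``y_m``, ``label`` and
    (for stratified verification) ``altitude_m``.  Plots outside a
    raster or on a nodata cell are excluded; the dropout report counts,
    per feature, how many rows that feature alone invalidated.
    """
    if groups is None:
        groups = {name: infer_group(name) for name in rasters}
    names = list(rasters)
    n = len(plots)
    values = np.full((n, len(names)), np.nan)
    inside = np.ones(n, dtype=bool)

    ref = rasters[names[0]]
    for other in rasters.values():
        ref.require_aligned(other)
    rows = np.empty(n, dtype=int)
    cols = np.empty(n, dtype=int)
    for i, (x, y) in enumerate(zip(plots["x_m"].to_numpy(), plots["y_m"].to_numpy())):
        r, c = ref.cell_at(x, y)
        if 0 <= r < ref.n_rows and 0 <= c < ref.n_cols:
            rows[i], cols[i] = r, c
        else:
            inside[i] = False
    if not inside.all():
        logger.warning("%d plots fall outside the raster grid and were excluded",
                       int((~inside).sum()))

    for j, name in enumerate(names):
        grid = rasters[name]
        data = np.asarray(grid.data, dtype=float)
        valid = grid.valid_mask
        vals = np.full(n, np.nan)
        vals[inside] = np.where(
            valid[rows[inside], cols[inside]], data[rows[inside], cols[inside]], np.nan
        )
        values[:, j] = vals

    nan_mask = np.isnan(values)
    dropout = {name: int(nan_mask[inside, j].sum()) for j, name in enumerate(names)}
    keep = inside & ~nan_mask.any(axis=1)
    dropped = plots.loc[~keep, "id"].tolist()
    if dropped:
        logger.info("dropped %d plot rows with missing features", len(dropped))

    index = pd.Index(plots.loc[keep, "id"].to_numpy(), name="plot_id")
    X = pd.DataFrame(values[keep], columns=names, index=index)
    y = pd.Series(plots.loc[keep, "label"].to_numpy().astype(int), index=index, name="label")
    alt = pd.Series(
        plots.loc[keep, "altitude_m"].to_numpy()
        if "altitude_m" in plots
        else np.full(keep.sum(), np.nan),
        index=index,
        name="altitude_m",
    )
    return FeatureMatrix(
        X=X, y=y, groups={n_: groups[n_] for n_ in names}, altitudes=alt,
        dropped_rows=dropped, dropout_report=dropout,
    )


def subset_by_group(fm: FeatureMatrix, groups: set[str] | list[str]) -> FeatureMatrix:
    """Column-filtered copy keeping only features in the given input sets."""
    groups = set(groups)
    if not groups:
        raise ValueError("groups must be non-empty")
    unknown = groups - set(KNOWN_GROUPS)
    if unknown:
        raise ValueError(f"unknown feature groups {sorted(unknown)}")
    cols = [c for c in fm.X.columns if fm.groups[c] in groups]
    return FeatureMatrix(
        X=fm.X[cols].copy(),
        y=fm.y.copy(),
        groups={c: fm.groups[c] for c in cols},
        altitudes=fm.altitudes.copy(),
        dropped_rows=list(fm.dropped_rows),
        dropout_report=dict(fm.dropout_report),
    )
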