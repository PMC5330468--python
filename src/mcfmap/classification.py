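"""Random-forest classification with recursive feature elimination.

The ensemble itself is scikit-learn's ``RandomForestClassifier``; this
module contributes the surrounding protocol:

* out-of-bag (OOB) predictions for verification — each training row is
  judged only by trees whose bootstrap sample excluded it, so the
  training points double as an independent validation set;
* Breiman-style OOB permutation importance: the drop in OOB accuracy
  when one feature column is permuted;
* recursive feature elimination (RFE): iteratively refit, rank by
  permutation importance, drop to the next subset size, and finally
  pick the smallest size whose OOB accuracy is within one standard
  error of the best;
* full-grid map prediction with strict nodata propagation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (  # reproduces each tree's bootstrap draw
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .features import FeatureMatrix
from .raster import RasterGrid

__all__ = [
    "TrainedModel",
    "oob_predictions",
    "oob_permutation_importance",
    "recursive_feature_elimination",
    "train",
    "predict_map",
]

logger = logging.getLogger(__name__)

DEFAULT_N_TREES = 500


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    selected_features: list[str]
    oob_predictions: np.ndarray  # per training row, binary
    oob_accuracy: float
    rfe_trace: pd.DataFrame | None
    seed: int


def _oob_vote_matrix(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Per-row class-probability votes restricted to OOB trees."""
    n = X.shape[0]
    votes = np.zeros((n, len(forest.classes_)))
    # fit uses no sample weights, so each tree's bootstrap draw is
    # reproducible from its random_state alone
    n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
    for est in forest.estimators_:
        idx = _generate_unsampled_indices(est.random_state, n, n_boot, None)
        if idx.size:
            votes[idx] += est.predict_proba(X[idx])
    return votes


def oob_predictions(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Majority-vote OOB class per training row.

    The rare row that appears in every bootstrap sample falls back to
    the in-bag prediction.
    """
    votes = _oob_vote_matrix(forest, X)
    never_oob = ~votes.any(axis=1)
    pred = forest.classes_[np.argmax(votes, axis=1)]
    if never_oob.any():
        pred[never_oob] = forest.predict(X[never_oob])
    return pred


def oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Decrease of OOB accuracy when one feature column is permuted."""
    rng = np.random.default_rng(seed)
    base = np.mean(oob_predictions(forest, X) == y)
    importance = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        Xp = X.copy()
        Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
        importance[j] = base - np.mean(oob_predictions(forest, Xp) == y)
    return importance


def _fit_forest(X: np.ndarray, y: np.ndarray, seed: int, n_trees: int) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return forest


def _default_size_schedule(n_features: int) -> list[int]:
    sizes = []
    s = n_features
    while s > 2:
        sizes.append(s)
        s = max(2, int(np.ceil(s * 2 / 3)))
    sizes.append(2)
    return sizes


def recursive_feature_elimination(
    fm: FeatureMatrix,
    sizes: list[int] | None = None,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[list[str], pd.DataFrame]:
    """Select a compact feature subset by iterative elimination.

    At each subset size a forest is fit, its OOB accuracy recorded, and
    the least important features (OOB permutation importance) dropped
    to reach the next size.  The returned subset is the smallest whose
    OOB accuracy is within one standard error of the best size
    (``se = sqrt(a (1 - a) / n)``).
    """
    names = fm.feature_names
    if len(names) < 2:
        raise ValueError("RFE needs at least 2 features")
    y = fm.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    if sizes is None:
        sizes = _default_size_schedule(len(names))
    sizes = sorted({int(s) for s in sizes if 1 <= s <= len(names)}, reverse=True)
    if not sizes:
        raise ValueError("empty size schedule")

    current = list(names)
    rows = []
    subsets: dict[int, list[str]] = {}
    for step, size in enumerate(sizes):
        if size < len(current):
            # drop least-important features from the previous fit's ranking
            current = [f for f in current if f in rows[-1]["ranking"][:size]]
        X = fm.X[current].to_numpy()
        forest = _fit_forest(X, y, seed, n_trees)
        acc = float(np.mean(oob_predictions(forest, X) == y))
        importance = oob_permutation_importance(forest, X, y, seed=seed + step)
        ranking = [current[j] for j in np.argsort(-importance, kind="stable")]
        rows.append({"size": len(current), "oob_accuracy": acc, "ranking": ranking})
        subsets[len(current)] = list(current)

    trace = pd.DataFrame(rows)
    best = trace["oob_accuracy"].max()
    se = float(np.sqrt(best * (1 - best) / len(y)))
    eligible = trace[trace["oob_accuracy"] >= best - se]
    chosen_size = int(eligible["size"].min())
    selected = subsets[chosen_size]
    logger.info("RFE selected %d/%d features (best OOB %.3f, 1-SE floor %.3f)",
                chosen_size, len(names), best, best - se)
    return selected, trace


def train(
    fm: FeatureMatrix,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    rfe_sizes: list[int] | None = None,
    run_rfe: bool = False,
    min_rows: int = 30,
) -> TrainedModel:
    """Fit the forest (optionally after RFE) and store OOB predictions."""
    if len(fm.y) < min_rows:
        raise ValueError(f"need at least {min_rows} training rows, got {len(fm.y)}")
    y = fm.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for training")
    trace = None
    selected = fm.feature_names
    if run_rfe:
        selected, trace = recursive_feature_elimination(fm, rfe_sizes, seed, n_trees)
    X = fm.X[selected].to_numpy()
    forest = _fit_forest(X, y, seed, n_trees)
    preds = oob_predictions(forest, X)
    return TrainedModel(
        forest=forest,
        selected_features=list(selected),
        oob_predictions=preds,
        oob_accuracy=float(np.mean(preds == y)),
        rfe_trace=trace,
        seed=seed,
    )


def predict_map(model: TrainedModel, rasters: dict[str, RasterGrid]) -> RasterGrid:
    """Per-cell majority-vote class map over the full grid.

    Cells where any selected feature is nodata stay nodata.
    """
    missing = [f for f in model.selected_features if f not in rasters]
    if missing:
        raise KeyError(f"missing feature rasters: {missing}")
    ref = rasters[model.selected_features[0]]
    stack = []
    valid = np.ones(ref.shape, dtype=bool)
    for name in model.selected_features:
        grid = rasters[name]
        ref.require_aligned(grid)
        stack.append(np.asarray(grid.data, dtype=float))
        valid &= grid.valid_mask
    X = np.stack(stack, axis=-1)[valid]
    out = np.full(ref.shape, np.nan)
    if X.shape[0]:
        out[valid] = model.forest.predict(X)
    return ref.with_data(out)
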