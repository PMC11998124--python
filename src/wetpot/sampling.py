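"""Balanced sampling, train/validation split, and random-forest classification.

Sampling is balanced between the wetland and non-wetland classes: the
per-class count is proportional to the valid area at a configurable
density (default one point per 475 km² per class), drawn uniformly
without replacement within each class. The split mimics a random-number
column: each point gets an independent uniform draw ``u`` and trains iff
``u < fraction``.

The classifier is a 200-tree random forest choosing among
``floor(sqrt(17)) = 4`` candidate features per node split, fitted on the
training points and applied cell-wise to the predictor stack.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_NAMES, FeatureStack
from .grids import Grid, GridError, INT_NODATA


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters."""

    n_trees: int = 200
    split_candidates: int = 4   # floor(sqrt(17))
    seed: int = 0
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise GridError("n_trees must be >= 1")
        if not (1 <= self.split_candidates <= len(FEATURE_NAMES)):
            raise GridError("split_candidates must be in [1, 17]")


@dataclass
class FittedModel:
    """Fitted ensemble plus raw per-feature importances.

    ``raw_importance`` is the mean impurity decrease attributed to each
    feature across trees (non-negative, ordered per
    :data:`~wetpot.features.FEATURE_NAMES`).
    """

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: RFConfig

    @property
    def raw_importance(self) -> np.ndarray:
        return self.estimator.feature_importances_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X).astype(np.int32)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def stratified_sample(labels: Grid, density_km2_per_point: float = 475.0,
                      seed: int = 0,
                      stack: FeatureStack | None = None) -> pd.DataFrame:
    """Balanced random sample of labeled cells.

    The per-class count is ``round(valid_area_km² / density)`` (half away
    from zero), capped at the class size with a warning. When ``stack`` is
    given, candidate cells are restricted to its complete-case mask and
    the 17 feature columns are attached.

    Returns a DataFrame with columns ``row, col, label`` (+ features).
    """
    if density_km2_per_point <= 0:
        raise GridError("density must be > 0")
    lab = np.asarray(labels.values)
    valid = labels.valid_mask()
    if stack is not None:
        if stack.shape != labels.shape:
            raise GridError("feature stack and labels have different shapes")
        valid = valid & stack.mask
    area_km2 = valid.sum() * labels.cell_size**2 / 1e6
    n_per_class = _round_half_away(area_km2 / density_km2_per_point)
    rng = np.random.default_rng(seed)

    frames = []
    for cls in (0, 1):
        rows, cols = np.nonzero(valid & (lab == cls))
        if rows.size == 0:
            raise GridError(f"class {cls} has no valid cells to sample")
        n = n_per_class
        if n > rows.size:
            warnings.warn(f"class {cls} has only {rows.size} cells; "
                          f"requested {n}", stacklevel=2)
            n = rows.size
        pick = rng.choice(rows.size, size=n, replace=False)
        frames.append(pd.DataFrame({"row": rows[pick], "col": cols[pick],
                                    "label": np.int32(cls)}))
    points = pd.concat(frames, ignore_index=True)
    if stack is not None:
        X = stack.matrix(points["row"].to_numpy(), points["col"].to_numpy())
        for j, name in enumerate(FEATURE_NAMES):
            points[name] = X[:, j]
    return points


def split_points(points: pd.DataFrame, fraction: float = 0.7,
                 seed: int = 0) -> pd.DataFrame:
    """Assign each point an independent uniform draw and a split label.

    ``split = "train"`` iff ``u < fraction``; the draw is stored in column
    ``u`` for audit. Returns a new DataFrame.
    """
    if not (0.0 < fraction < 1.0):
        raise GridError("split fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = points.copy()
    out["u"] = rng.uniform(size=len(out))
    out["split"] = np.where(out["u"] < fraction, "train", "validation")
    return out


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

def fit_rf(train: pd.DataFrame, cfg: RFConfig = RFConfig()) -> FittedModel:
    """Fit the random forest on training points.

    Trees are grown on bootstrap resamples to purity (subject to
    ``min_leaf``), choosing among ``split_candidates`` randomly selected
    features per node; prediction is by majority vote.
    """
    if len(train) == 0:
        raise GridError("empty training set")
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise GridError("training set contains a single class")
    X = train[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=cfg.split_candidates,
        min_samples_leaf=cfg.min_leaf,
        bootstrap=True,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return FittedModel(est, FEATURE_NAMES, cfg)


def predict_map(model: FittedModel, stack: FeatureStack) -> Grid:
    """Apply the model cell-wise; masked cells become nodata."""
    rows, cols = np.nonzero(stack.mask)
    out = np.full(stack.shape, INT_NODATA, dtype=np.int32)
    if rows.size:
        X = stack.matrix(rows, cols)
        out[rows, cols] = model.predict(X)
    ref = stack.layers[FEATURE_NAMES[0]]
    return ref.like(out, units="")


def normalized_importance(model: FittedModel) -> pd.Series:
    """Raw importances rescaled to sum to 1, keyed by feature name."""
    raw = np.asarray(model.raw_importance, dtype=np.float64)
    total = raw.sum()
    if total <= 0:
        raise GridError("all raw importances are zero")
    return pd.Series(raw / total, index=list(model.feature_names),
                     name="normalized_importance")
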