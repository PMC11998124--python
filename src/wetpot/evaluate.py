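"""Confusion-matrix accuracy assessment on reserved validation points.

Conventions follow the standard remote-sensing accuracy vocabulary:
commission error (CE) is the fraction of cells predicted as a class that
do not belong to it; omission error (OE) is the fraction of a class's
true cells the prediction missed; overall accuracy (OA) is the diagonal
fraction. All three are reported as percentages; ratios with a zero
denominator are reported as not-applicable (None).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridError
from .sampling import FittedModel
from .features import FEATURE_NAMES


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts: truth (wetland=1 / non-wetland=0) vs. prediction."""

    n11: int  # truth wetland,     predicted wetland
    n10: int  # truth wetland,     predicted non-wetland
    n01: int  # truth non-wetland, predicted wetland
    n00: int  # truth non-wetland, predicted non-wetland

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise GridError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def score_points(model: FittedModel, validation: pd.DataFrame) -> ConfusionMatrix:
    """Tally truth vs. model prediction over validation points."""
    if len(validation) == 0:
        raise GridError("empty validation set")
    X = validation[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    pred = model.predict(X)
    truth = validation["label"].to_numpy()
    return ConfusionMatrix(
        n11=int(np.sum((truth == 1) & (pred == 1))),
        n10=int(np.sum((truth == 1) & (pred == 0))),
        n01=int(np.sum((truth == 0) & (pred == 1))),
        n00=int(np.sum((truth == 0) & (pred == 0))),
    )


def accuracy_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Overall accuracy and per-class commission/omission error, in percent.

    Keys: ``overall_accuracy``, ``wetland_ce``, ``wetland_oe``,
    ``nonwetland_ce``, ``nonwetland_oe``. Undefined ratios are None.
    """
    if cm.total == 0:
        raise GridError("empty confusion matrix")

    def pct(num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    return {
        "overall_accuracy": pct(cm.n11 + cm.n00, cm.total),
        "wetland_ce": pct(cm.n01, cm.n11 + cm.n01),
        "wetland_oe": pct(cm.n10, cm.n11 + cm.n10),
        "nonwetland_ce": pct(cm.n10, cm.n00 + cm.n10),
        "nonwetland_oe": pct(cm.n01, cm.n00 + cm.n01),
    }


def metrics_table(metrics: dict[str, float | None]) -> str:
    """Plain-text accuracy table, one decimal place per entry."""

    def fmt(v: float | None) -> str:
        return "n/a" if v is None else f"{v:.1f}"

    lines = [
        "class        CE      OE",
        f"non-wetland  {fmt(metrics['nonwetland_ce']):>6}  {fmt(metrics['nonwetland_oe']):>6}",
        f"wetland      {fmt(metrics['wetland_ce']):>6}  {fmt(metrics['wetland_oe']):>6}",
        f"overall accuracy: {fmt(metrics['overall_accuracy'])}",
    ]
    return "\n".join(lines)
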