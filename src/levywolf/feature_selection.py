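"""Pearson-correlation feature ranking against a binary outcome.

Each feature's importance is the absolute sample Pearson correlation
between the feature column and the 0/1 label — numerically identical to
the point-biserial correlation between the feature and the two outcome
groups.  The top-k features by importance form the reduced table used
for model training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledTable

__all__ = ["FeatureRanking", "pearson_r", "rank_features"]


@dataclass
class FeatureRanking:
    """Top-k features ordered by non-increasing |Pearson r|."""

    names: list[str]
    importances: np.ndarray
    k: int
    constant_flags: list[bool] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_name": self.names, "feature_value": self.importances}
        )


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share length >= 2")
    # constant vectors have undefined correlation; test range, not the
    # centered sum of squares, which can be a nonzero rounding residue
    if x.max() == x.min() or y.max() == y.min():
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc))
    if denom == 0:
        return float("nan")
    return float(np.sum(xc * yc) / denom)


def rank_features(data: LabeledTable, k: int) -> tuple[FeatureRanking, LabeledTable]:
    """Rank features by |r| with the label and keep the top k.

    Constant features score 0 (flagged) instead of erroring; ties keep
    original column order (stable sort).  Returns the ranking and the
    reduced table, both in rank order.
    """
    if not 1 <= k <= data.n_features:
        raise ValueError(f"k must be in [1, {data.n_features}], got {k}")
    y = data.labels.astype(float)
    importances = np.empty(data.n_features)
    flags = []
    for j in range(data.n_features):
        r = pearson_r(data.features[:, j], y)
        if np.isnan(r):
            importances[j] = 0.0
            flags.append(True)
        else:
            importances[j] = abs(r)
            flags.append(False)
    order = np.argsort(-importances, kind="stable")[:k]
    ranking = FeatureRanking(
        names=[data.feature_names[j] for j in order],
        importances=importances[order],
        k=k,
        constant_flags=[flags[j] for j in order],
    )
    return ranking, data.select(list(order))
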