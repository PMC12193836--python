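"""Labeled tabular data container and CSV I/O.

A :class:`LabeledTable` is the in-memory form of every classification
dataset the package touches: an ``n x p`` float feature matrix plus a
binary 0/1 outcome vector.  On disk it is a plain comma-separated file
with a header row and the outcome in a trailing ``label`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclass
class LabeledTable:
    """Numeric feature matrix with binary outcome labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must be one value per sample")
        if not np.isfinite(self.features).all():
            raise ValueError("missing or non-finite feature values are not permitted")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, got {sorted(uniq)}")
        self.labels = self.labels.astype(int)
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def select(self, columns: list[int]) -> "LabeledTable":
        """Return a copy restricted to the given feature columns (in order)."""
        return LabeledTable(
            features=self.features[:, columns].copy(),
            labels=self.labels.copy(),
            feature_names=[self.feature_names[j] for j in columns],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        return df


def save_csv(table: LabeledTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_csv(path) -> LabeledTable:
    """Load a labeled table; the last column must be named ``label``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"data file has no '{LABEL_COLUMN}' column")
    if df.isna().any().any():
        raise ValueError("data file contains missing values")
    labels = df[LABEL_COLUMN].to_numpy()
    feats = df.drop(columns=[LABEL_COLUMN])
    return LabeledTable(
        features=feats.to_numpy(dtype=float),
        labels=labels,
        feature_names=list(feats.columns),
    )
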