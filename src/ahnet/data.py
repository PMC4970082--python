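"""Labeled tabular dataset container shared by the readers and generators."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError


@dataclass(frozen=True)
class LabeledDataset:
    """A Q x N feature table with one label per row.

    Features are a named-column DataFrame (cells may be NaN, the missing
    marker); labels are an object/int array of class identifiers.
    """

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self):
        if self.features.shape[0] < 1 or self.features.shape[1] < 1:
            raise InvalidInputError("features must be a non-empty Q x N table")
        labels = np.asarray(self.labels)
        if labels.shape != (self.features.shape[0],):
            raise InvalidInputError("labels length must equal the feature row count")
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self, label_column: str = "activity") -> pd.DataFrame:
        frame = self.features.copy()
        frame[label_column] = self.labels
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label_column: str = "activity") -> "LabeledDataset":
        if label_column not in frame.columns:
            raise InvalidInputError(f"label column {label_column!r} not in table")
        features = frame.drop(columns=[label_column])
        return cls(features.reset_index(drop=True), frame[label_column].to_numpy())
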