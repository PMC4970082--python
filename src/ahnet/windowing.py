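"""Majority-voting recognition over fixed windows of sensor streams.

A recognition system does not classify isolated samples: the fixed-rate
stream of one activity is cut into windows (default 2.5 s at 100 Hz =
250 samples, no overlap), every sample in the window is classified, and
the window's activity is the most frequent per-sample prediction.  When
per-sample errors are independent and below 1/2, the windowed (binomial
majority) accuracy exceeds the per-sample accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .classifier import AHNClassifierModel, predict_codes
from .errors import InvalidInputError
from .metrics import ConfusionMatrix


@dataclass(frozen=True)
class ActivityStream:
    """Time-ordered T x N feature block for one (subject, activity)."""

    subject_id: object
    activity_label: object
    features: pd.DataFrame
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise InvalidInputError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry in samples; overlap must be smaller than the size."""

    size_samples: int = 250
    overlap_samples: int = 0

    def __post_init__(self):
        if self.size_samples < 1:
            raise InvalidInputError("size_samples must be >= 1")
        if not (0 <= self.overlap_samples < self.size_samples):
            raise InvalidInputError("overlap must be in [0, size)")

    @property
    def stride(self) -> int:
        return self.size_samples - self.overlap_samples

    @classmethod
    def from_seconds(cls, seconds: float, sample_rate: float, overlap_seconds: float = 0.0) -> "WindowSpec":
        return cls(int(round(seconds * sample_rate)), int(round(overlap_seconds * sample_rate)))


def n_windows(n_samples: int, spec: WindowSpec) -> int:
    """floor((T - size) / stride) + 1 for T >= size, else 0."""
    if n_samples < spec.size_samples:
        return 0
    return (n_samples - spec.size_samples) // spec.stride + 1


def segment(stream: ActivityStream, spec: WindowSpec) -> list[pd.DataFrame]:
    """Cut the stream into windows; a trailing partial window is dropped."""
    out = []
    for w in range(n_windows(stream.n_samples, spec)):
        start = w * spec.stride
        out.append(stream.features.iloc[start : start + spec.size_samples])
    return out


def majority_vote(values):
    """Most frequent value in a window; ties go to the smallest value
    (for integer codes: the smallest numeric code)."""
    values = list(values)
    if not values:
        raise InvalidInputError("cannot vote on an empty window")
    counts = Counter(values)
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def evaluate_windowed(
    model: AHNClassifierModel, streams, spec: WindowSpec = WindowSpec()
) -> ConfusionMatrix:
    """Windowed recognition: per-sample codes -> per-window votes -> one
    confusion count per window (rows predicted, columns actual)."""
    j = model.label_map.n_classes
    counts = np.zeros((j, j), dtype=np.int64)
    for stream in streams:
        actual = int(model.label_map.encode([stream.activity_label])[0])
        codes = predict_codes(model, stream.features)
        for w in range(n_windows(stream.n_samples, spec)):
            start = w * spec.stride
            vote = majority_vote(codes[start : start + spec.size_samples].tolist())
            counts[vote - 1, actual - 1] += 1
    return ConfusionMatrix(counts, model.label_map.ordered_labels)


def streams_to_frame(streams) -> pd.DataFrame:
    """Serialize streams to one long table (subject, activity, features),
    preserving time order within each stream."""
    parts = []
    for s in streams:
        part = s.features.copy()
        part.insert(0, "subject", s.subject_id)
        part.insert(1, "activity", s.activity_label)
        part.insert(2, "sample_rate", s.sample_rate)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def streams_from_frame(frame: pd.DataFrame) -> list[ActivityStream]:
    """Inverse of :func:`streams_to_frame`; row order is time order."""
    required = {"subject", "activity"}
    if not required.issubset(frame.columns):
        raise InvalidInputError("stream table needs 'subject' and 'activity' columns")
    streams = []
    keys = frame[["subject", "activity"]].drop_duplicates().itertuples(index=False)
    for subject, activity in keys:
        block = frame[(frame["subject"] == subject) & (frame["activity"] == activity)]
        rate = float(block["sample_rate"].iloc[0]) if "sample_rate" in block else 100.0
        feats = block.drop(columns=[c for c in ("subject", "activity", "sample_rate") if c in block])
        streams.append(ActivityStream(subject, activity, feats.reset_index(drop=True), rate))
    return streams
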