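"""Reader, cleaner and stratified sampler for PAMAP2 raw files.

PAMAP2 (Physical Activity Monitoring) records 9 subjects performing 18
activities while wearing three "Colibri" inertial measurement units
(hand, chest, ankle) sampled at 100 Hz plus a heart-rate monitor.  Each
raw ``.dat`` line has 54 space-separated columns: timestamp (s), activity
id (0 marks transient/rest periods), heart rate (bpm), then 17 channels
per IMU — temperature, 3D acceleration at +/-16 g, 3D acceleration at
+/-6 g, 3D gyroscope (rad/s), 3D magnetometer (uT) and 4 orientation
values.  (The orientation block has four entries; the 54-column
arithmetic and the published feature index 51 are only consistent with
four.)

Cleaning removes transient rows and the timestamp/heart-rate bookkeeping
columns, retaining the 51 inertial features.  The dataset itself is never
downloaded here; every downstream stage also runs on synthetic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import InsufficientDataError, InvalidInputError, MalformedLineError

N_RAW_COLUMNS = 54
N_FEATURES = 51
ACTIVITIES_WITH_LARGE_POOLS = 12  # activity ids 1..12 get the larger samples

_IMU_CHANNELS = (
    ["temperature"]
    + [f"acc16_{ax}" for ax in "xyz"]
    + [f"acc6_{ax}" for ax in "xyz"]
    + [f"gyro_{ax}" for ax in "xyz"]
    + [f"mag_{ax}" for ax in "xyz"]
    + [f"orient_{i}" for i in range(1, 5)]
)

#: Names of all 54 raw columns, in file order.
RAW_COLUMNS = tuple(
    ["timestamp", "activity_id", "heart_rate"]
    + [f"{imu}_{ch}" for imu in ("hand", "chest", "ankle") for ch in _IMU_CHANNELS]
)

#: 1-based raw column number -> feature name (hand 4-20, chest 21-37, ankle 38-54).
FEATURE_NUMBER_TO_NAME = {i + 1: name for i, name in enumerate(RAW_COLUMNS) if i >= 3}

#: Feature-column presets by name.  ``rfe10`` is the published 10-feature
#: subset retained by recursive feature elimination (shipped as a fixed
#: preset; the elimination itself is not re-run here).
FEATURE_PRESETS = {
    "all51": tuple(RAW_COLUMNS[3:]),
    "rfe10": tuple(FEATURE_NUMBER_TO_NAME[i] for i in (4, 21, 24, 27, 32, 33, 38, 48, 50, 51)),
}


def read_pamap2_file(path) -> pd.DataFrame:
    """Parse one subject's space-separated raw file into a 54-column table.

    Literal ``NaN`` tokens become missing markers.  A line with the wrong
    token count raises :class:`MalformedLineError` naming the line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != N_RAW_COLUMNS:
                raise MalformedLineError(path, lineno, len(tokens), N_RAW_COLUMNS)
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise MalformedLineError(path, lineno, len(tokens), N_RAW_COLUMNS) from exc
    return pd.DataFrame(rows, columns=list(RAW_COLUMNS))


def write_pamap2_file(frame: pd.DataFrame, path) -> None:
    """Write a 54-column table back to the raw space-separated format."""
    if list(frame.columns) != list(RAW_COLUMNS):
        raise InvalidInputError("frame does not have the 54 raw columns")
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(" ".join("NaN" if np.isnan(v) else repr(float(v)) for v in row) + "\n")


def clean(records: pd.DataFrame, drop_missing: bool = True) -> LabeledDataset:
    """Remove transient (activity 0) rows and bookkeeping columns.

    The timestamp and heart-rate columns are dropped (51 inertial
    features retained); with ``drop_missing`` every row containing a
    missing feature is discarded.  Labels are the integer activity ids.
    """
    kept = records[records["activity_id"] != 0]
    features = kept.drop(columns=["timestamp", "activity_id", "heart_rate"])
    labels = kept["activity_id"].astype(int)
    if drop_missing:
        mask = features.notna().all(axis=1)
        features, labels = features[mask], labels[mask]
    if features.shape[0] == 0:
        raise InsufficientDataError("no rows left after cleaning")
    return LabeledDataset(features.reset_index(drop=True), labels.to_numpy())


@dataclass(frozen=True)
class SamplingScheme:
    """Per-activity train/test counts for stratified sampling.

    The default mirrors the case-study scheme: 600 training and 300
    testing samples for each of the first twelve activities, 500 and 250
    for the rest.
    """

    train_large: int = 600
    train_small: int = 500
    test_large: int = 300
    test_small: int = 250
    seed: int = 0

    def counts(self, activity) -> tuple[int, int]:
        large = int(activity) <= ACTIVITIES_WITH_LARGE_POOLS
        return (self.train_large, self.test_large) if large else (self.train_small, self.test_small)


def stratified_sample(dataset: LabeledDataset, scheme: SamplingScheme) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded per-activity sampling without replacement into disjoint
    train and test sets.  Raises naming the activity when its pool is
    too small."""
    rng = np.random.default_rng(scheme.seed)
    train_idx, test_idx = [], []
    for activity in sorted(set(dataset.labels.tolist())):
        pool = np.flatnonzero(dataset.labels == activity)
        n_train, n_test = scheme.counts(activity)
        if pool.size < n_train + n_test:
            raise InsufficientDataError(
                f"activity {activity!r} has {pool.size} rows, needs {n_train + n_test}"
            )
        chosen = rng.choice(pool, size=n_train + n_test, replace=False)
        train_idx.append(chosen[:n_train])
        test_idx.append(chosen[n_train:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    return (
        LabeledDataset(dataset.features.iloc[train_idx].reset_index(drop=True), dataset.labels[train_idx]),
        LabeledDataset(dataset.features.iloc[test_idx].reset_index(drop=True), dataset.labels[test_idx]),
    )


def select_features(dataset: LabeledDataset, preset: str) -> LabeledDataset:
    """Restrict a cleaned dataset to a named feature preset."""
    if preset not in FEATURE_PRESETS:
        raise InvalidInputError(f"unknown feature preset {preset!r}")
    names = [c for c in FEATURE_PRESETS[preset] if c in dataset.features.columns]
    if len(names) != len(FEATURE_PRESETS[preset]):
        raise InvalidInputError("dataset lacks columns required by the preset")
    return LabeledDataset(dataset.features[names].copy(), dataset.labels)
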