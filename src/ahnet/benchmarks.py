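"""Published reference results of the AHN classifier on the PAMAP2 benchmark.

These are the printed results of the original PAMAP2 evaluation of the
AHN activity classifier, stored as data so consistency checks (recomputing
accuracy and macro sensitivity from the raw confusion counts, recomputing
cross-experiment means and standard deviations from the per-dataset
scores) can run without any external download.  Nothing here is produced
by this package's own training code.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix

#: The 18 benchmark activities in activity-id order.
ACTIVITY_NAMES = (
    "Lying",
    "Sitting",
    "Standing",
    "Walking",
    "Running",
    "Cycling",
    "Nordic walking",
    "Watching TV",
    "Computer work",
    "Car driving",
    "Ascending stairs",
    "Descending stairs",
    "Vacuum cleaning",
    "Ironing",
    "Folding laundry",
    "House cleaning",
    "Playing soccer",
    "Rope jumping",
)

#: Per-sample confusion counts (rows predicted, columns actual) of the AHN
#: classifier on the first 30 s of every activity of every subject
#: (105 streams x 3000 samples = 315,000 scored samples).
SAMPLEWISE_CONFUSION_COUNTS = np.array(
    [
        [23985, 19, 1, 22, 30, 7, 13, 3, 0, 6, 0, 10, 0, 0, 0, 0, 3, 0],
        [13, 23567, 6, 22, 8, 1, 1, 0, 0, 0, 0, 4, 0, 0, 0, 0, 0, 1],
        [0, 20, 23542, 30, 10, 5, 11, 0, 0, 0, 1, 4, 0, 0, 0, 0, 0, 0],
        [2, 109, 48, 23567, 19, 16, 38, 0, 0, 0, 7, 8, 0, 0, 0, 0, 0, 0],
        [0, 133, 47, 70, 14760, 14, 78, 0, 0, 0, 7, 11, 1, 0, 0, 0, 1, 0],
        [0, 47, 75, 85, 19, 20616, 66, 0, 0, 0, 10, 21, 1, 0, 0, 0, 1, 1],
        [0, 74, 129, 134, 32, 120, 20676, 0, 65, 3, 43, 41, 14, 2, 0, 7, 3, 1],
        [0, 4, 69, 31, 26, 73, 35, 2961, 35, 10, 27, 29, 17, 2, 0, 19, 1, 1],
        [0, 4, 18, 17, 21, 51, 21, 33, 11790, 7, 37, 31, 31, 9, 3, 18, 2, 0],
        [0, 7, 12, 6, 22, 37, 14, 0, 37, 2957, 49, 50, 41, 20, 1, 27, 4, 2],
        [0, 1, 6, 1, 10, 21, 19, 0, 36, 4, 23638, 55, 66, 42, 9, 11, 6, 2],
        [0, 0, 2, 3, 10, 10, 10, 0, 17, 1, 64, 23569, 72, 72, 12, 33, 8, 8],
        [0, 0, 17, 3, 17, 12, 13, 0, 20, 2, 90, 103, 23684, 190, 70, 90, 30, 40],
        [0, 7, 26, 0, 4, 0, 0, 0, 0, 0, 7, 16, 30, 23592, 34, 34, 8, 20],
        [0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 6, 20, 24, 41, 11820, 27, 15, 15],
        [0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 2, 8, 14, 19, 22, 14690, 11, 14],
        [0, 0, 0, 0, 4, 0, 0, 0, 0, 0, 6, 12, 5, 9, 28, 32, 5883, 69],
        [0, 8, 2, 8, 4, 17, 5, 3, 0, 10, 6, 8, 0, 2, 1, 12, 24, 14826],
    ],
    dtype=np.int64,
)

#: Windowed (2.5 s, majority vote) confusion diagonal: the number of
#: 30-second windows per activity, i.e. 12 windows per performing subject.
WINDOWED_DIAGONAL = (96, 96, 96, 96, 60, 84, 84, 12, 48, 12, 96, 96, 96, 96, 48, 60, 24, 60)

#: Number of subjects that performed each activity for at least 30 s.
SUBJECTS_PER_ACTIVITY = (8, 8, 8, 8, 5, 7, 7, 1, 4, 1, 8, 8, 8, 8, 4, 5, 2, 5)

#: AHN accuracy on the three headline experiments (complete dataset,
#: 7%-noise dataset, reduced feature set) and the matching micro-F1 values.
ACCURACY_BY_EXPERIMENT = {"complete": 0.9829, "noise07": 0.9696, "reduced": 0.9741}
F1_MICRO_BY_EXPERIMENT = {"complete": 0.9910, "noise07": 0.9839, "reduced": 0.9864}

#: AHN accuracy / micro-F1 across the three noise levels.
ACCURACY_BY_NOISE = {0.07: 0.9696, 0.15: 0.9547, 0.30: 0.8786}
F1_MICRO_BY_NOISE = {0.07: 0.9839, 0.15: 0.9781, 0.30: 0.9470}


def samplewise_confusion() -> ConfusionMatrix:
    """The per-sample reference confusion matrix as a package object."""
    return ConfusionMatrix(SAMPLEWISE_CONFUSION_COUNTS.copy(), ACTIVITY_NAMES)


def windowed_confusion() -> ConfusionMatrix:
    """The (perfectly diagonal) windowed reference confusion matrix."""
    return ConfusionMatrix(np.diag(np.asarray(WINDOWED_DIAGONAL, dtype=np.int64)), ACTIVITY_NAMES)
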