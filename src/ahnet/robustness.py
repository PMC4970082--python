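"""Noise-tolerance protocol: random removal of feature cells + mean imputation.

The protocol corrupts only the *testing* feature matrix: a fraction p of
all feature cells (jointly over the whole matrix, labels untouched) is
deleted uniformly at random, then every missing cell is replaced by the
mean of the observed values in its own column of the corrupted matrix.
Because deleted cells are replaced with a column statistic, the procedure
amounts to random noise insertion at rate p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnimputableColumnError

#: Corruption fractions of the case-study benchmark.
CASE_STUDY_FRACTIONS = (0.07, 0.15, 0.30)


@dataclass(frozen=True)
class NoiseSpec:
    """Cell-deletion fraction p in [0, 1] and the draw seed."""

    fraction: float
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise InvalidInputError("fraction must be in [0, 1]")


def _split_frame(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), features.columns, features.index
    return np.asarray(features, dtype=float), None, None


def _join_frame(X, columns, index):
    if columns is not None:
        return pd.DataFrame(X, columns=columns, index=index)
    return X


def inject_missing(features, spec: NoiseSpec):
    """Mark exactly ``floor(p * Q * N)`` distinct cells as missing.

    Cells are chosen uniformly without replacement over the whole matrix,
    seeded.  Returns (corrupted matrix, number of cells marked).  The
    input must not already contain missing cells.
    """
    X, columns, index = _split_frame(features)
    if X.ndim != 2:
        raise InvalidInputError("features must be a Q x N matrix")
    if np.isnan(X).any():
        raise InvalidInputError("matrix already contains missing cells")
    q, n = X.shape
    n_cells = math.floor(spec.fraction * q * n)
    rng = np.random.default_rng(spec.seed)
    flat = rng.choice(q * n, size=n_cells, replace=False)
    out = X.copy()
    out[np.unravel_index(flat, (q, n))] = np.nan
    return _join_frame(out, columns, index), n_cells


def impute_column_mean(features):
    """Replace each missing cell with its own column's observed mean.

    Observed cells are untouched; a matrix without missing cells is
    returned unchanged (as a copy).  A fully-missing column cannot be
    imputed and raises.
    """
    X, columns, index = _split_frame(features)
    if X.ndim != 2:
        raise InvalidInputError("features must be a Q x N matrix")
    out = X.copy()
    missing = np.isnan(out)
    for j in np.flatnonzero(missing.any(axis=0)):
        observed = out[~missing[:, j], j]
        if observed.size == 0:
            name = columns[j] if columns is not None else j
            raise UnimputableColumnError(f"column {name!r} has no observed values")
        out[missing[:, j], j] = observed.mean()
    return _join_frame(out, columns, index)


def corrupt_and_impute(features, fraction: float, seed: int = 0):
    """Convenience composition of the protocol: inject then impute.

    Returns (imputed matrix, number of corrupted cells).  One corrupted
    dataset is fixed per (fraction, seed) pair.
    """
    corrupted, count = inject_missing(features, NoiseSpec(fraction, seed))
    return impute_column_mean(corrupted), count
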