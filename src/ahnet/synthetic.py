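"""Seeded synthetic-data generators for every input shape of the pipeline.

Three generators cover the system end to end without any download:

* :func:`gen_piecewise` — scalar (z, y) pairs from a known in-family
  piecewise polynomial (ground truth for parameter-recovery studies);
* :func:`gen_classes` — a multiclass sensor-like feature table with
  Gaussian class clusters whose means are equally spaced along one latent
  unit direction (the ordered-classes structure the numeric-label
  classifier assumes);
* :func:`gen_streams` — fixed-rate per-(subject, activity) streams drawn
  from the same class distributions, for the windowing experiments.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import InvalidInputError
from .windowing import ActivityStream


@dataclass(frozen=True)
class PiecewiseSpec:
    """Ground-truth piecewise polynomial: strictly increasing bounds and
    one descending-power coefficient vector per interval.  Outer
    intervals may be cubic, inner ones quadratic (model-family
    compatible)."""

    bounds: tuple[float, ...]
    coefficients: tuple[tuple[float, ...], ...]
    noise_sd: float = 0.0

    def __post_init__(self):
        bounds = tuple(float(b) for b in self.bounds)
        coeffs = tuple(tuple(float(c) for c in cs) for cs in self.coefficients)
        if len(bounds) != len(coeffs) + 1:
            raise InvalidInputError("need exactly one coefficient set per interval")
        if not all(b0 < b1 for b0, b1 in zip(bounds, bounds[1:])):
            raise InvalidInputError("bounds must be strictly increasing")
        degrees = [len(c) - 1 for c in coeffs]
        limits = [3] + [2] * (len(coeffs) - 2) + [3] if len(coeffs) >= 2 else [3] * len(coeffs)
        if any(d > lim for d, lim in zip(degrees, limits)):
            raise InvalidInputError("interval degree exceeds the model family (outer <= 3, inner <= 2)")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        object.__setattr__(self, "bounds", bounds)
        object.__setattr__(self, "coefficients", coeffs)

    def true_values(self, zs) -> np.ndarray:
        zs = np.asarray(zs, dtype=float)
        edges = np.asarray(self.bounds)
        idx = np.clip(np.searchsorted(edges, zs, side="right") - 1, 0, len(self.coefficients) - 1)
        out = np.empty_like(zs)
        for j, coeffs in enumerate(self.coefficients):
            sel = idx == j
            if np.any(sel):
                out[sel] = np.polyval(coeffs, zs[sel])
        return out


def gen_piecewise(spec: PiecewiseSpec, n_samples: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform z over the spec domain; y = interval polynomial + Gaussian
    noise of sd ``spec.noise_sd``."""
    rng = np.random.default_rng(seed)
    zs = rng.uniform(spec.bounds[0], spec.bounds[-1], size=n_samples)
    ys = spec.true_values(zs)
    if spec.noise_sd > 0:
        ys = ys + rng.normal(0.0, spec.noise_sd, size=n_samples)
    return zs, ys


@dataclass(frozen=True)
class ClassSpec:
    """Multi-class cluster geometry emulating a per-activity feature table.

    Class j (codes 1..J) has mean ``j * axis_separation * u`` for a fixed
    latent unit direction u (drawn once from the seed) plus isotropic
    Gaussian noise.  The default separation/noise ratio of 6 keeps
    within-class spread at 1/6 of the class spacing.
    """

    n_classes: int = 18
    samples_per_class: int = 200
    n_features: int = 51
    axis_separation: float = 6.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidInputError("need at least two classes")
        if self.samples_per_class < 1 or self.n_features < 1:
            raise InvalidInputError("samples_per_class and n_features must be >= 1")
        if self.noise_sd < 0 or self.axis_separation <= 0:
            raise InvalidInputError("axis_separation must be > 0 and noise_sd >= 0")


def _latent_direction(seed: int, n_features: int) -> np.ndarray:
    # substream 0 of the spec seed: shared by gen_classes and gen_streams
    u = np.random.default_rng([seed, 0]).normal(size=n_features)
    return u / np.linalg.norm(u)


def _feature_names(n: int) -> list[str]:
    return [f"f{i:02d}" for i in range(1, n + 1)]


def gen_classes(spec: ClassSpec, noise_seed: int = 0) -> LabeledDataset:
    """Generate the labeled feature table; labels are integer codes 1..J.

    The latent direction depends only on ``spec.seed``; the per-sample
    noise additionally depends on ``noise_seed``, so tables generated
    with different ``noise_seed`` are independent draws from the *same*
    class distributions (train/test pairs).
    """
    u = _latent_direction(spec.seed, spec.n_features)
    rng = np.random.default_rng([spec.seed, 1, noise_seed])
    blocks, labels = [], []
    for j in range(1, spec.n_classes + 1):
        mean = j * spec.axis_separation * u
        noise = rng.normal(0.0, 1.0, size=(spec.samples_per_class, spec.n_features))
        blocks.append(mean + spec.noise_sd * noise)
        labels.extend([j] * spec.samples_per_class)
    X = np.vstack(blocks)
    return LabeledDataset(pd.DataFrame(X, columns=_feature_names(spec.n_features)), np.asarray(labels))


def class_means(spec: ClassSpec) -> tuple[np.ndarray, np.ndarray]:
    """The latent direction u and the J class mean vectors (J x N)."""
    u = _latent_direction(spec.seed, spec.n_features)
    means = np.outer(np.arange(1, spec.n_classes + 1) * spec.axis_separation, u)
    return u, means


def gen_streams(
    spec: ClassSpec,
    subjects: int,
    duration_seconds: float = 30.0,
    hz: float = 100.0,
) -> list[ActivityStream]:
    """One fixed-rate stream per (subject, activity), each sample drawn
    i.i.d. from the activity's class distribution.

    The latent direction is derived from the seed exactly as in
    :func:`gen_classes`, so a classifier trained on the table generator's
    output is distributionally matched to these streams.
    """
    if subjects < 1:
        raise InvalidInputError("need at least one subject")
    u = _latent_direction(spec.seed, spec.n_features)
    t = int(round(duration_seconds * hz))
    names = _feature_names(spec.n_features)
    streams = []
    for subject in range(1, subjects + 1):
        for j in range(1, spec.n_classes + 1):
            rng = np.random.default_rng([spec.seed, 2, subject, j])
            mean = j * spec.axis_separation * u
            X = mean + spec.noise_sd * rng.normal(0.0, 1.0, size=(t, spec.n_features))
            streams.append(ActivityStream(subject, j, pd.DataFrame(X, columns=names), hz))
    return streams
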