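"""Numeric-label activity classifier built on the AHN regression core.

Classes are encoded as consecutive integer codes 1..J (deterministic
lexicographic label order) and the compound regresses the projected
feature axis onto those codes; prediction decodes psi(z) by nearest
integer code.  Because similar codes sit on adjacent intervals,
misclassifications concentrate on neighbouring codes — an inherent
property of the numeric-label scheme.

Multivariate inputs are reduced to the single scalar axis the piecewise
model requires by a standardized first-principal-axis projection (an
explicit, persisted design choice of this package); alternatively a
single named feature can serve as the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Compound, TrainingConfig, TrainingTrace, compound_values, train_compound
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    MissingValuesError,
    UnknownLabelError,
)


@dataclass(frozen=True)
class LabelMap:
    """Bijection between the J class identifiers and integer codes 1..J."""

    ordered_labels: tuple

    def __post_init__(self):
        labels = tuple(self.ordered_labels)
        if len(labels) == 0:
            raise InvalidInputError("label map needs at least one label")
        if len(set(labels)) != len(labels):
            raise InvalidInputError("labels must be distinct")
        object.__setattr__(self, "ordered_labels", labels)
        object.__setattr__(self, "_code_of", {lab: i + 1 for i, lab in enumerate(labels)})

    @property
    def n_classes(self) -> int:
        return len(self.ordered_labels)

    def encode(self, labels) -> np.ndarray:
        codes = np.empty(len(labels), dtype=int)
        for i, lab in enumerate(labels):
            try:
                codes[i] = self._code_of[lab]
            except KeyError:
                raise UnknownLabelError(lab) from None
        return codes

    def decode(self, codes) -> np.ndarray:
        codes = np.asarray(codes, dtype=int)
        if np.any(codes < 1) or np.any(codes > self.n_classes):
            raise UnknownLabelError("code out of range")
        return np.asarray([self.ordered_labels[c - 1] for c in codes])


def build_label_map(labels) -> LabelMap:
    """Distinct labels in deterministic sorted order, coded 1..J."""
    return LabelMap(tuple(sorted(set(labels))))


@dataclass(frozen=True)
class ProjectionSpec:
    """First-principal-axis projection onto a scalar z.

    z = ((x - means) / scales) . loadings, with unit-norm loadings whose
    largest-magnitude entry is fixed positive (sign anchor) so the axis
    orientation is reproducible.  Zero-variance columns get scale 1 and
    contribute nothing.
    """

    means: tuple[float, ...]
    scales: tuple[float, ...]
    loadings: tuple[float, ...]
    sign_anchor: int
    feature_names: tuple[str, ...] = ()

    def __post_init__(self):
        means = tuple(float(v) for v in self.means)
        scales = tuple(float(v) for v in self.scales)
        loadings = tuple(float(v) for v in self.loadings)
        if not (len(means) == len(scales) == len(loadings)):
            raise InvalidInputError("means, scales and loadings lengths differ")
        if any(s <= 0 for s in scales):
            raise InvalidInputError("scales must be positive")
        if abs(float(np.linalg.norm(loadings)) - 1.0) > 1e-12:
            raise InvalidInputError("loadings must have unit norm")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "loadings", loadings)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_features(self) -> int:
        return len(self.means)


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def fit_projection(features, feature_names=(), standardize: bool = False) -> ProjectionSpec:
    """Center columns and take the first principal axis as loadings.

    With ``standardize`` each column is also divided by its standard
    deviation before the axis is extracted (appropriate when features
    carry heterogeneous units).  The default keeps the raw covariance
    geometry: when class clusters are isotropic, per-column scaling
    shrinks exactly the high-signal columns and can halve the projected
    class separation, so it is opt-in rather than automatic.
    """
    X = _as_matrix(features)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("projection needs a Q x N matrix with Q >= 2")
    if np.isnan(X).any():
        raise MissingValuesError("feature matrix has missing cells; impute first")
    means = X.mean(axis=0)
    if standardize:
        scales = X.std(axis=0)
        scales[scales == 0.0] = 1.0
    else:
        scales = np.ones(X.shape[1])
    Z = (X - means) / scales
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    anchor = int(np.argmax(np.abs(loadings)))
    if loadings[anchor] < 0:
        loadings = -loadings
    loadings = loadings / np.linalg.norm(loadings)
    if isinstance(features, pd.DataFrame) and not feature_names:
        feature_names = tuple(map(str, features.columns))
    return ProjectionSpec(tuple(means), tuple(scales), tuple(loadings), anchor, feature_names)


def project(spec: ProjectionSpec, features) -> np.ndarray:
    """Apply the projection row-wise, returning the scalar axis z."""
    X = _as_matrix(features)
    X = np.atleast_2d(X)
    if X.shape[1] != spec.n_features:
        raise InvalidInputError(
            f"feature dimension {X.shape[1]} does not match projection ({spec.n_features})"
        )
    Z = (X - np.asarray(spec.means)) / np.asarray(spec.scales)
    return Z @ np.asarray(spec.loadings)


@dataclass
class AHNClassifierModel:
    """Deployable classifier: projection + trained compound + label map."""

    projection: ProjectionSpec
    compound: Compound
    label_map: LabelMap
    config: TrainingConfig
    training_trace: TrainingTrace | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.compound.n_molecules != self.config.n_molecules:
            raise InvalidInputError("compound molecule count must match config.n_molecules")


def train_classifier(
    features, labels, config: TrainingConfig | None = None, *, standardize: bool = False
) -> AHNClassifierModel:
    """Train the full classifier on a labeled feature table.

    The compound size defaults to the number of classes J (one molecule
    per activity is the recommended, though empirical, choice); pass an
    explicit config to override.  Seeded and deterministic.
    """
    X = _as_matrix(features)
    if np.isnan(X).any():
        raise MissingValuesError("feature matrix has missing cells; impute first")
    label_map = build_label_map(labels)
    if config is None:
        config = TrainingConfig(n_molecules=max(label_map.n_classes, 2))
    projection = fit_projection(features, standardize=standardize)
    z = project(projection, features)
    y = label_map.encode(labels).astype(float)
    compound, trace = train_compound(z, y, config)
    return AHNClassifierModel(projection, compound, label_map, config, trace)


def decision_values(model: AHNClassifierModel, features) -> np.ndarray:
    """Raw regression outputs psi(z) before decoding."""
    return compound_values(model.compound, project(model.projection, features))


def predict_codes(model: AHNClassifierModel, features) -> np.ndarray:
    """Nearest-integer decoding of psi(z), ties toward the lower code,
    clipped to [1, J]."""
    psi = decision_values(model, features)
    codes = np.ceil(psi - 0.5).astype(int)  # half-codes round down
    return np.clip(codes, 1, model.label_map.n_classes)


def predict_labels(model: AHNClassifierModel, features) -> np.ndarray:
    """Predicted class labels (always labels present in the label map)."""
    return model.label_map.decode(predict_codes(model, features))
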