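"""JSON persistence for trained models.

The document stores the canonical coefficient vectors plus the derived
chemistry view (carbon values, hydrogens as re/im pairs), the projection,
the label map, the training config and provenance (seed, iterations,
final error).  Floats are serialized with full round-trip precision, so
load(save(m)) predicts identically to m.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np

from .classifier import AHNClassifierModel, LabelMap, ProjectionSpec
from .core import Compound, MoleculeParams, TrainingConfig
from .errors import SchemaVersionError
from . import __version__

SCHEMA = "ahnet-model/1"


def _molecule_doc(mol: MoleculeParams) -> dict:
    return {
        "degree": mol.degree,
        "coefficients": list(mol.coefficients),
        "carbon_value": mol.carbon_value,
        "hydrogens": [[h.real, h.imag] for h in mol.hydrogens],
    }


def model_to_doc(model: AHNClassifierModel) -> dict:
    trace = model.training_trace
    doc = {
        "schema": SCHEMA,
        "version": __version__,
        "label_map": list(model.label_map.ordered_labels),
        "projection": {
            "means": list(model.projection.means),
            "scales": list(model.projection.scales),
            "loadings": list(model.projection.loadings),
            "sign_anchor": model.projection.sign_anchor,
            "feature_names": list(model.projection.feature_names),
        },
        "compound": {
            "bounds": list(model.compound.bounds),
            "molecules": [_molecule_doc(m) for m in model.compound.molecules],
        },
        "config": {
            "n_molecules": model.config.n_molecules,
            "learning_rate": model.config.learning_rate,
            "tolerance": model.config.tolerance,
            "max_iterations": model.config.max_iterations,
            "seed": model.config.seed,
            "min_samples_per_interval": model.config.min_samples_per_interval,
            "min_distance_fraction": model.config.min_distance_fraction,
        },
    }
    if trace is not None:
        doc["provenance"] = {
            "iterations": len(trace),
            "best_iteration": trace.best_iteration,
            "final_rmse": trace.records[-1].rmse if trace.records else math.nan,
            "best_rmse": trace.best_rmse,
        }
    return doc


def model_from_doc(doc: dict) -> AHNClassifierModel:
    if doc.get("schema") != SCHEMA:
        raise SchemaVersionError(f"unsupported model schema {doc.get('schema')!r}")
    proj = doc["projection"]
    comp = doc["compound"]
    labels = doc["label_map"]
    molecules = tuple(
        MoleculeParams(tuple(m["coefficients"]), m["degree"]) for m in comp["molecules"]
    )
    return AHNClassifierModel(
        projection=ProjectionSpec(
            tuple(proj["means"]),
            tuple(proj["scales"]),
            tuple(proj["loadings"]),
            int(proj["sign_anchor"]),
            tuple(proj.get("feature_names", ())),
        ),
        compound=Compound(molecules, tuple(comp["bounds"])),
        label_map=LabelMap(tuple(labels)),
        config=TrainingConfig(**doc["config"]),
    )


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")


def save_model(model: AHNClassifierModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_doc(model), indent=2, default=_json_default) + "\n")


def load_model(path) -> AHNClassifierModel:
    return model_from_doc(json.loads(Path(path).read_text()))
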