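"""The seven classifier families behind one train/predict contract.

Families: artificial neural network (one hidden layer), decision tree,
linear discriminant analysis, linear SVM, k-nearest neighbors, random
forest, and RBF-kernel SVM (quadratic discriminant analysis is available
as an optional extra). All are scikit-learn estimators; a trained model
travels as a :class:`ModelBundle` holding the estimator together with its
fitted normalizer, feature names and label vocabulary, so prediction on
new tables is self-contained.

Stochastic families (ANN, random forest, linear SVM) are seeded through
``ModelSpec.random_seed`` and reproduce bit-identical predictions.
"""
from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import BundleLoadError, ModelError
from .features import NormalizationParams, apply_normalizer, fit_normalizer
from .io import FeatureTable

BUNDLE_FORMAT_VERSION = 1

#: The seven supported families, by canonical short name.
FAMILIES: tuple[str, ...] = ("ann", "tree", "lda", "linsvm", "knn", "rf", "rbfsvm")

_ALIASES: dict[str, str] = {
    "ann": "ann", "mlp": "ann",
    "tree": "tree", "decisiontree": "tree", "decision_tree": "tree",
    "lda": "lda",
    "linsvm": "linsvm", "linearsvm": "linsvm", "linear_svm": "linsvm",
    "knn": "knn", "nearestneighbors": "knn", "nearest_neighbors": "knn",
    "rf": "rf", "randomforest": "rf", "random_forest": "rf",
    "rbfsvm": "rbfsvm", "rbf_svm": "rbfsvm",
    "qda": "qda",
}

DEFAULT_HYPERPARAMETERS: dict[str, dict[str, Any]] = {
    "ann": {"hidden_layer_sizes": (10,), "activation": "logistic",
            "max_iter": 500},
    "tree": {"criterion": "gini", "max_depth": None},
    "lda": {"solver": "svd"},
    "linsvm": {"C": 1.0},
    "knn": {"n_neighbors": 5},
    "rf": {"n_estimators": 100},
    "rbfsvm": {"C": 1.0, "gamma": "auto"},  # gamma = 1 / n_features
    "qda": {},
}


def canonical_family(name: str) -> str:
    key = name.strip().lower().replace("-", "_")
    key = _ALIASES.get(key) or _ALIASES.get(key.replace("_", ""))
    if key is None:
        raise ModelError(f"unknown model family {name!r}; choose from {FAMILIES}")
    return key


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus hyperparameter overrides and a seed."""

    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)
    random_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", canonical_family(self.family))

    def resolved_hyperparameters(self) -> dict[str, Any]:
        params = dict(DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


def build_estimator(spec: ModelSpec):
    """Construct an unfitted scikit-learn estimator for a spec."""
    p = spec.resolved_hyperparameters()
    seed = spec.random_seed
    if isinstance(p.get("hidden_layer_sizes"), list):
        p["hidden_layer_sizes"] = tuple(p["hidden_layer_sizes"])
    if spec.family == "ann":
        return MLPClassifier(random_state=seed, **p)
    if spec.family == "tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if spec.family == "lda":
        return LinearDiscriminantAnalysis(**p)
    if spec.family == "linsvm":
        return LinearSVC(random_state=seed, **p)
    if spec.family == "knn":
        return KNeighborsClassifier(**p)
    if spec.family == "rf":
        return RandomForestClassifier(random_state=seed, **p)
    if spec.family == "rbfsvm":
        return SVC(kernel="rbf", random_state=seed, **p)
    if spec.family == "qda":
        return QuadraticDiscriminantAnalysis(**p)
    raise ModelError(f"unknown family {spec.family!r}")


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to apply it."""

    spec: ModelSpec
    estimator: Any
    normalizer: NormalizationParams
    feature_names: list[str]
    label_vocabulary: list[str]  # sorted behavior names


def train(spec: ModelSpec, table: FeatureTable,
          normalizer: NormalizationParams | None = None) -> ModelBundle:
    """Fit one classifier on a labeled feature table.

    Unless a pre-fitted ``normalizer`` is supplied, a z-score normalizer is
    fitted on ``table`` and stored in the bundle; prediction re-applies it,
    so callers pass raw (un-normalized) feature tables throughout.
    """
    if table.labels is None:
        raise ModelError("training table has no labels")
    vocab = sorted(set(table.labels))
    if len(vocab) < 2:
        raise ModelError("training table has a single class; need at least 2")
    if table.n_rows < len(vocab):
        raise ModelError(
            f"{table.n_rows} rows for {len(vocab)} classes; need at least one per class"
        )
    if normalizer is None:
        normalizer = fit_normalizer(table)
    X = apply_normalizer(normalizer, table).values
    index = {label: i for i, label in enumerate(vocab)}
    y = np.asarray([index[label] for label in table.labels])
    estimator = build_estimator(spec)
    estimator.fit(X, y)
    return ModelBundle(spec=spec, estimator=estimator, normalizer=normalizer,
                       feature_names=list(table.feature_names),
                       label_vocabulary=vocab)


def predict(bundle: ModelBundle, table: FeatureTable) -> list[str]:
    """Label each row of an (un-normalized) feature table.

    Feature names must match the bundle exactly; any labels on the table
    are ignored. Returns one behavior name per row, drawn from the
    bundle's vocabulary.
    """
    if list(table.feature_names) != list(bundle.feature_names):
        missing = sorted(set(bundle.feature_names) - set(table.feature_names))
        extra = sorted(set(table.feature_names) - set(bundle.feature_names))
        raise ModelError(
            f"feature names do not match bundle: missing {missing}, "
            f"unexpected {extra}"
        )
    if table.n_rows == 0:
        return []
    X = apply_normalizer(bundle.normalizer, table).values
    y = bundle.estimator.predict(X)
    return [bundle.label_vocabulary[int(i)] for i in y]


def training_accuracy(bundle: ModelBundle, table: FeatureTable) -> float:
    """Fraction of a labeled table the bundle labels correctly."""
    if table.labels is None:
        raise ModelError("table has no labels to score against")
    preds = predict(bundle, table)
    return float(np.mean([p == t for p, t in zip(preds, table.labels)]))


# ---------------------------------------------------------------------------
# Persistence: zip archive with a JSON manifest + joblib estimator state
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist a bundle as a single archive (manifest + estimator state)."""
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "family": bundle.spec.family,
        "hyperparameters": dict(bundle.spec.hyperparameters),
        "random_seed": bundle.spec.random_seed,
        "feature_names": list(bundle.feature_names),
        "label_vocabulary": list(bundle.label_vocabulary),
        "normalizer": bundle.normalizer.to_dict(),
    }
    buf = _io.BytesIO()
    joblib.dump(bundle.estimator, buf)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        zf.writestr("estimator.joblib", buf.getvalue())


def read_manifest(path: str | Path) -> dict:
    """Read only the JSON manifest of a saved bundle (for audit)."""
    try:
        with zipfile.ZipFile(path) as zf:
            return json.loads(zf.read("manifest.json"))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as exc:
        raise BundleLoadError(f"cannot read bundle {path}: {exc}") from exc


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a bundle saved by :func:`save_bundle`.

    Raises :class:`BundleLoadError` on corrupt archives or unknown format
    versions rather than returning a partially loaded model.
    """
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            estimator_bytes = zf.read("estimator.joblib")
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError) as exc:
        raise BundleLoadError(f"cannot read bundle {path}: {exc}") from exc
    version = manifest.get("format_version")
    if version != BUNDLE_FORMAT_VERSION:
        raise BundleLoadError(
            f"bundle format version {version!r} not supported "
            f"(expected {BUNDLE_FORMAT_VERSION})"
        )
    try:
        estimator = joblib.load(_io.BytesIO(estimator_bytes))
        spec = ModelSpec(manifest["family"], manifest["hyperparameters"],
                         manifest["random_seed"])
        normalizer = NormalizationParams.from_dict(manifest["normalizer"])
        return ModelBundle(spec=spec, estimator=estimator, normalizer=normalizer,
                           feature_names=list(manifest["feature_names"]),
                           label_vocabulary=list(manifest["label_vocabulary"]))
    except (KeyError, ValueError, EOFError) as exc:
        raise BundleLoadError(f"bundle {path} is corrupt: {exc}") from exc
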