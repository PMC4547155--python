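"""Classifier training, persistence and prediction.

Three model kinds are exposed:

* ``zeror`` — the majority-class baseline (ties break toward the
  smallest label code);
* ``gaussian_nb`` — Gaussian naive Bayes;
* ``decision_tree`` — a C4.5-style tree (information-based splits,
  minimum leaf size, optional cost-complexity pruning).  This is the
  default recognizer for the activity model.

Induction for the tree and naive Bayes is delegated to scikit-learn;
this module pins down the contract: determinism given (data, spec with
seed), the class list, feature-name checking at prediction time, and a
versioned on-disk format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainedModel",
    "ModelIOError",
    "train",
    "predict",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("zeror", "gaussian_nb", "decision_tree")

_FORMAT = "harkit-model"
_VERSION = 1


class ModelIOError(IOError):
    """Raised when a model file cannot be read or is not ours."""


@dataclass(frozen=True)
class ModelSpec:
    """What to train and with which hyperparameters.

    ``min_leaf`` and ``prune`` apply to the decision tree only
    (minimum samples per leaf, and whether cost-complexity pruning with
    a small alpha is applied); the seed fixes any tie-breaking so
    training is reproducible.
    """

    kind: str = "decision_tree"
    seed: int = 0
    min_leaf: int = 2
    prune: bool = True
    ccp_alpha: float = 1e-3

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


@dataclass
class TrainedModel:
    spec: ModelSpec
    classes: np.ndarray
    feature_names: tuple[str, ...]
    impl: Any  # fitted sklearn estimator, or the modal label for zeror


def train(features: FeatureMatrix, spec: ModelSpec) -> TrainedModel:
    """Fit a model on a feature matrix; deterministic given the spec."""
    if features.n_windows == 0:
        raise ValueError("cannot train on an empty feature matrix")
    X, y = features.values, features.labels
    classes = np.unique(y)

    if spec.kind == "zeror":
        # np.unique sorts ascending, argmax takes the first maximum, so
        # ties resolve to the smallest label code.
        counts = np.array([(y == c).sum() for c in classes])
        impl = int(classes[np.argmax(counts)])
    elif spec.kind == "gaussian_nb":
        impl = GaussianNB().fit(X, y)
    else:  # decision_tree
        impl = DecisionTreeClassifier(
            criterion="entropy",
            min_samples_leaf=spec.min_leaf,
            ccp_alpha=spec.ccp_alpha if spec.prune else 0.0,
            random_state=spec.seed,
        ).fit(X, y)
    return TrainedModel(
        spec=spec, classes=classes, feature_names=features.feature_names, impl=impl
    )


def predict(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Predict one label per row; only training classes can appear."""
    if features.feature_names != model.feature_names:
        raise ValueError("feature names do not match the training matrix")
    return predict_values(model, features.values)


def predict_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Predict from a raw (rows x features) array (column order assumed)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
        )
    if model.spec.kind == "zeror":
        return np.full(X.shape[0], model.impl, dtype=np.int64)
    return model.impl.predict(X).astype(np.int64)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a versioned, self-describing archive."""
    payload = {
        "format": _FORMAT,
        "version": _VERSION,
        "spec": model.spec,
        "classes": model.classes,
        "feature_names": model.feature_names,
        "impl": model.impl,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    """Load a model archive; refuses foreign or incompatible files."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt or not a joblib file
        raise ModelIOError(f"{path}: cannot read model file ({exc})") from None
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT:
        raise ModelIOError(f"{path}: not a harkit model file")
    if payload.get("version") != _VERSION:
        raise ModelIOError(
            f"{path}: model format version {payload.get('version')!r} "
            f"not supported (expected {_VERSION})"
        )
    return TrainedModel(
        spec=payload["spec"],
        classes=payload["classes"],
        feature_names=tuple(payload["feature_names"]),
        impl=payload["impl"],
    )
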