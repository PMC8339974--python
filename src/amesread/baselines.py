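"""Global baseline classifiers behind one train/predict contract.

Five families, each with the fixed hyperparameters of the benchmark
configuration and otherwise the implementing library's defaults:

* ``random_forest`` — 1,000 trees, max_leaf_nodes 200.
* ``logistic_sgd_ensemble`` — five logistic models trained by stochastic
  gradient descent for 50 epochs; probabilities averaged.
* ``logistic_default`` — logistic regression at library defaults.
* ``neural_net_ensemble`` — five multilayer perceptrons (four hidden
  layers of 64 ReLU units, Adam, batch size 64, 50 epochs); probabilities
  averaged.
* ``svm_rbf`` — RBF-kernel support vector machine, gamma="scale".

Ensemble members differ only by random initialization (distinct seeds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

FAMILIES = (
    "random_forest",
    "logistic_sgd_ensemble",
    "logistic_default",
    "neural_net_ensemble",
    "svm_rbf",
)
_ENSEMBLE_SIZE = 5


@dataclass
class ModelSpec:
    """A model family plus hyperparameter overrides and a seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")


def _build_members(spec: ModelSpec) -> list:
    hp = dict(spec.hyperparameters)
    if spec.family == "random_forest":
        return [
            RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 1000),
                max_leaf_nodes=hp.pop("max_leaf_nodes", 200),
                random_state=spec.seed,
                **hp,
            )
        ]
    if spec.family == "logistic_sgd_ensemble":
        return [
            SGDClassifier(
                loss="log_loss",
                max_iter=hp.get("epochs", 50),
                tol=None,
                shuffle=True,
                random_state=spec.seed + i,
            )
            for i in range(_ENSEMBLE_SIZE)
        ]
    if spec.family == "logistic_default":
        return [LogisticRegression(random_state=spec.seed, **hp)]
    if spec.family == "neural_net_ensemble":
        return [
            MLPClassifier(
                hidden_layer_sizes=hp.get("hidden_layer_sizes", (64, 64, 64, 64)),
                activation="relu",
                solver="adam",
                batch_size=hp.get("batch_size", 64),
                max_iter=hp.get("epochs", 50),
                random_state=spec.seed + i,
            )
            for i in range(_ENSEMBLE_SIZE)
        ]
    if spec.family == "svm_rbf":
        return [
            SVC(
                kernel="rbf",
                gamma="scale",
                probability=True,
                random_state=spec.seed,
                **hp,
            )
        ]
    raise AssertionError(spec.family)


class FittedModel:
    """A trained family with its feature vocabulary.

    ``predict_proba`` returns the probability of the mutagenic (positive)
    class; the class call is ``p >= 0.5``.  Feature columns at prediction
    time must match the training columns by name and order.
    """

    def __init__(self, spec: ModelSpec, members: list, feature_names: list[str]):
        self.spec = spec
        self.members = members
        self.feature_names = feature_names

    def _check_columns(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise ValueError(
                "feature columns do not match training columns "
                f"({len(features.columns)} vs {len(self.feature_names)})"
            )
        return features.to_numpy(dtype=float)

    def member_probabilities(self, features: pd.DataFrame) -> np.ndarray:
        """Per-member positive-class probabilities, shape (n_members, n)."""
        x = self._check_columns(features)
        rows = []
        for m in self.members:
            pos = list(m.classes_).index(1)
            rows.append(m.predict_proba(x)[:, pos])
        return np.vstack(rows)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return self.member_probabilities(features).mean(axis=0)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(features) >= 0.5).astype(int)

    def resolved_hyperparameters(self) -> dict:
        """All resolved member parameters, for the run manifest."""
        return {f"member_{i}": m.get_params() for i, m in enumerate(self.members)}

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedModel":
        return joblib.load(path)


def train(spec: ModelSpec, features: pd.DataFrame, labels: np.ndarray) -> FittedModel:
    """Train one family on a binary label vector (1 = mutagenic).

    Deterministic given the spec's seed.  Raises when only one class is
    present — none of the families can calibrate a probability then.
    """
    y = np.asarray(labels, dtype=int)
    if len(features) != len(y):
        raise ValueError("features and labels disagree in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    members = _build_members(spec)
    x = features.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # SVC(probability=True) is the fixed benchmark configuration; newer
        # scikit-learn raises a FutureWarning steering toward calibration.
        warnings.simplefilter("ignore", FutureWarning)
        for m in members:
            m.fit(x, y)
    return FittedModel(spec, members, list(features.columns))
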