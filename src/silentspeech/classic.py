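"""Feature-based classifiers and the validation-set grid-search protocol.

Three standard estimator families are compared on the engineered features:
a margin classifier (SVM), a single decision tree, and a random forest.
Hyperparameters are chosen by exhaustive grid search scored by accuracy on
the *validation* partition (not cross-validation — the protocol keeps one
fixed 60/20/20 split); ties go to the first configuration in grid order,
and the winning configuration is refit on the training partition.

Features are standardised (train-partition mean/variance) for the SVM only;
trees are scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import ParameterGrid
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

MODEL_FAMILIES = ("svm", "dt", "rf")

#: Default grids; continuous parameters span orders of magnitude.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {
        "clf__C": [0.01, 0.1, 1.0, 10.0, 100.0],
        "clf__kernel": ["rbf", "linear", "poly"],
        "clf__gamma": [0.001, 0.01, 0.1, 1.0],
    },
    "dt": {
        "clf__max_depth": [3, 5, 10, None],
        "clf__min_samples_leaf": [1, 5, 10],
    },
    "rf": {
        "clf__n_estimators": [100, 300],
        "clf__max_depth": [None, 10],
        "clf__max_features": ["sqrt", None],
    },
}


@dataclass(frozen=True)
class GridSearchSpec:
    """What to search: model family, grid, seed."""
    model_family: str
    grid: Mapping[str, Sequence] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.model_family!r}; expected {MODEL_FAMILIES}")
        g = self.grid if self.grid is not None else DEFAULT_GRIDS[self.model_family]
        if not g or any(len(v) == 0 for v in g.values()):
            raise ValueError("hyperparameter grid must be non-empty")

    @property
    def effective_grid(self) -> dict:
        return dict(self.grid) if self.grid is not None \
            else DEFAULT_GRIDS[self.model_family]


@dataclass
class ScenarioResult:
    """Evaluation record of one trained model on one test partition."""
    accuracy: float                 # percent
    macro_f1: float                 # percent
    confusion: np.ndarray           # (n_classes, n_classes) counts
    labels: list[str]               # row/column order of the confusion matrix
    chosen_params: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)


def make_pipeline(family: str, seed: int = 0) -> Pipeline:
    """Base pipeline for a family (scaler only where the model needs it)."""
    if family == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(random_state=seed))])
    if family == "dt":
        return Pipeline([("clf", DecisionTreeClassifier(random_state=seed))])
    if family == "rf":
        return Pipeline([("clf", RandomForestClassifier(random_state=seed,
                                                        n_jobs=1))])
    raise ValueError(f"unknown model family {family!r}")


def grid_search_train(X_train, y_train, X_val, y_val, spec: GridSearchSpec
                      ) -> tuple[Pipeline, dict, list[tuple[dict, float]]]:
    """Exhaustive grid search scored on the validation partition.

    Returns (fitted best pipeline, best parameters, full validation trace).
    The trace has one ``(params, val_accuracy)`` entry per grid point, in
    grid order; the best entry is the first reaching the maximum accuracy.
    The returned model is refit on the training partition only.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(np.unique(y_train)) < 2:
        raise ValueError("need at least 2 classes in the training partition")

    base = make_pipeline(spec.model_family, spec.seed)
    trace: list[tuple[dict, float]] = []
    best_acc = -1.0
    best_params: dict = {}
    for params in ParameterGrid(spec.effective_grid):
        est = clone(base).set_params(**params)
        est.fit(X_train, y_train)
        acc = float(accuracy_score(y_val, est.predict(X_val)))
        trace.append((dict(params), acc))
        if acc > best_acc:  # strict: ties keep the earlier grid point
            best_acc = acc
            best_params = dict(params)
    model = clone(base).set_params(**best_params)
    model.fit(X_train, y_train)
    return model, best_params, trace


def evaluate(model, X_test, y_test, labels: Sequence[str] | None = None
             ) -> ScenarioResult:
    """Accuracy (%), macro-F1 (%) and confusion matrix on the test partition."""
    y_test = np.asarray(y_test)
    classes = list(labels) if labels is not None \
        else sorted(np.unique(y_test).tolist())
    train_classes = set(np.asarray(model.classes_).tolist()) \
        if hasattr(model, "classes_") else None
    if train_classes is not None:
        unseen = set(y_test.tolist()) - train_classes
        if unseen:
            raise ValueError(f"test labels never seen in training: {sorted(unseen)}")
    pred = model.predict(X_test)  # models own their input coercion
    cm = confusion_matrix(y_test, pred, labels=classes)
    return ScenarioResult(
        accuracy=100.0 * float(accuracy_score(y_test, pred)),
        macro_f1=100.0 * float(f1_score(y_test, pred, average="macro",
                                        labels=classes, zero_division=0)),
        confusion=cm,
        labels=classes,
    )


class GridSearchClassifier(BaseEstimator, ClassifierMixin):
    """Estimator wrapper: fit runs the validation grid search.

    ``fit(X, y, X_val=..., y_val=...)`` requires the validation partition;
    fitted attributes expose the chosen configuration and the trace.
    """

    def __init__(self, model_family: str = "rf",
                 grid: Mapping | None = None, random_state: int = 0):
        self.model_family = model_family
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        if X_val is None or y_val is None:
            raise ValueError("GridSearchClassifier needs X_val/y_val")
        spec = GridSearchSpec(self.model_family, self.grid, self.random_state)
        self.model_, self.best_params_, self.validation_trace_ = \
            grid_search_train(X, y, X_val, y_val, spec)
        self.classes_ = self.model_.classes_
        return self

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))
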