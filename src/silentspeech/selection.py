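"""Recursive feature elimination with a validation-selected subset.

Backward elimination: starting from all d features, fit an importance
estimator, drop the single least-important feature, and repeat until one
feature remains.  The full elimination order is recorded.  The *selected*
subset is then chosen by walking the nested subsets along the elimination
path, scoring each on a held-out validation partition, and returning the
smallest subset whose validation accuracy is within a tolerance (default
0.5 percentage points) of the best — the point of the procedure is
dimensionality reduction, so ties go to the smaller subset.

Importance sources: ``"forest"`` (impurity importance of a random-forest
fit; scale-free, the default) or ``"linear_svm"`` (sum of squared weights
of a linear margin classifier, features standardised internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


@dataclass
class FeatureRanking:
    """Full elimination record plus the validation-selected subset.

    ``elimination_round[f]`` is the iteration (1-based) at which feature
    ``f`` was dropped; the sole survivor gets round ``d``.  Rounds are a
    permutation of 1..d.  ``ranking`` lists features best-first (survivor
    first).  ``validation_trace`` maps subset size -> validation accuracy
    (filled by :func:`select_subset`).
    """
    ranking: list[str]
    elimination_round: dict[str, int]
    selected: list[str] = field(default_factory=list)
    validation_trace: dict[int, float] = field(default_factory=dict)


def _importance(X: np.ndarray, y: np.ndarray, source: str, seed: int
                ) -> np.ndarray:
    if source == "forest":
        est = RandomForestClassifier(n_estimators=100, random_state=seed,
                                     n_jobs=1)
        est.fit(X, y)
        return est.feature_importances_
    if source == "linear_svm":
        Xs = StandardScaler().fit_transform(X)
        est = LinearSVC(dual=False, random_state=seed)
        est.fit(Xs, y)
        return np.sum(est.coef_ ** 2, axis=0)
    raise ValueError(f"unknown importance source {source!r}")


def rfe_rank(features: pd.DataFrame | np.ndarray, labels: Sequence,
             importance_source: str = "forest", seed: int = 0
             ) -> FeatureRanking:
    """Rank all features by backward elimination (one drop per iteration)."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(labels)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are constant; ranking is undefined")

    remaining = list(range(X.shape[1]))
    elimination_round: dict[str, int] = {}
    rnd = 1
    while len(remaining) > 1:
        imp = _importance(X[:, remaining], y, importance_source, seed)
        # drop the least important; ties go to the lower column index so the
        # procedure is deterministic
        worst_local = int(np.lexsort((remaining, imp))[0])
        dropped = remaining.pop(worst_local)
        elimination_round[names[dropped]] = rnd
        rnd += 1
    elimination_round[names[remaining[0]]] = rnd
    ranking = sorted(names, key=lambda f: -elimination_round[f])
    return FeatureRanking(ranking=ranking, elimination_round=elimination_round)


def select_subset(ranking: FeatureRanking,
                  train_features: pd.DataFrame | np.ndarray,
                  train_labels: Sequence,
                  val_features: pd.DataFrame | np.ndarray,
                  val_labels: Sequence,
                  tolerance: float = 0.005,
                  seed: int = 0) -> list[str]:
    """Pick the smallest subset along the elimination path within
    ``tolerance`` of the best validation accuracy.

    Subsets are the nested prefixes of ``ranking.ranking`` (best-first), so
    subset size k = the k features eliminated last.  Fills
    ``ranking.validation_trace`` and ``ranking.selected`` in place and
    returns the selected feature names.
    """
    Xtr, names = _as_matrix(train_features)
    Xva, names_v = _as_matrix(val_features)
    if names != names_v:
        raise ValueError("train and validation feature columns differ")
    if len(Xva) == 0:
        raise ValueError("validation partition is empty")
    ytr = np.asarray(train_labels)
    yva = np.asarray(val_labels)

    col = {f: i for i, f in enumerate(names)}
    trace: dict[int, float] = {}
    for k in range(1, len(ranking.ranking) + 1):
        subset = ranking.ranking[:k]
        idx = [col[f] for f in subset]
        est = RandomForestClassifier(n_estimators=100, random_state=seed,
                                     n_jobs=1)
        est.fit(Xtr[:, idx], ytr)
        trace[k] = float(np.mean(est.predict(Xva[:, idx]) == yva))
    best = max(trace.values())
    k_sel = min(k for k, acc in trace.items() if acc >= best - tolerance)
    ranking.validation_trace = trace
    ranking.selected = ranking.ranking[:k_sel]
    return ranking.selected


def _as_matrix(features) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


class RecursiveFeatureEliminator(BaseEstimator):
    """sklearn-style selector: fit ranks features and picks the subset.

    Parameters
    ----------
    importance_source : {"forest", "linear_svm"}
    tolerance : float
        Validation-accuracy slack (fraction, default 0.005 = 0.5 pp) within
        which the smallest subset wins.
    random_state : int

    Attributes (after fit)
    ----------------------
    ranking_ : FeatureRanking
    selected_ : list of selected feature names
    support_ : boolean mask over input columns
    """

    def __init__(self, importance_source: str = "forest",
                 tolerance: float = 0.005, random_state: int = 0):
        self.importance_source = importance_source
        self.tolerance = tolerance
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
        else:
            names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
        self.ranking_ = rfe_rank(X, y, self.importance_source,
                                 self.random_state)
        if X_val is not None:
            self.selected_ = select_subset(
                self.ranking_, X, y, X_val, y_val,
                tolerance=self.tolerance, seed=self.random_state)
        else:
            self.selected_ = list(self.ranking_.ranking)
        self.feature_names_in_ = names
        self.support_ = np.array([f in set(self.selected_) for f in names])
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.selected_]
        return np.asarray(X)[:, self.support_]
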