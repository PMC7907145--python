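"""Classical baselines: RBF-kernel SVM, KNN, and logistic regression.

Input vectors are the flattened per-trial feature frames (windows x channels
x bands), standardized on the training portion.  Hyperparameters are
grid-searched; the reported score is tenfold cross-validation accuracy.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["baseline_fit", "BASELINE_METHODS"]

BASELINE_METHODS = ("svm", "knn", "logreg")


def _make_search(method: str, seed: int, inner_cv: int) -> GridSearchCV:
    if method == "svm":
        estimator = SVC(kernel="rbf")
        grid: Dict = {"model__C": [0.1, 1.0, 10.0, 100.0], "model__gamma": ["scale", 0.01, 0.001]}
    elif method == "knn":
        estimator = KNeighborsClassifier(metric="euclidean")
        grid = {"model__n_neighbors": [1, 3, 5, 7, 9]}
    elif method == "logreg":
        estimator = LogisticRegression(max_iter=2000)
        grid = {"model__C": np.logspace(-2, 3, 6).tolist()}
    else:
        raise ValueError(f"unknown baseline method {method!r}; choose from {BASELINE_METHODS}")
    pipe = Pipeline([("scale", StandardScaler()), ("model", estimator)])
    return GridSearchCV(
        pipe,
        grid,
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        n_jobs=1,
    )


def baseline_fit(
    features: np.ndarray,
    labels: np.ndarray,
    method: str,
    seed: int = 0,
    cv: int = 10,
) -> Tuple[GridSearchCV, float]:
    """Fit one baseline and report its ``cv``-fold cross-validation accuracy.

    Returns the classifier fitted on all data (hyperparameters grid-searched
    internally) and the mean cross-validated accuracy.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if features.ndim != 2:
        raise ValueError("features must be 2-D (samples x dimensions)")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    search = _make_search(method, seed, 3)
    outer = StratifiedKFold(cv, shuffle=True, random_state=seed)
    scores = cross_val_score(search, features, labels, cv=outer, n_jobs=1)
    fitted = search.fit(features, labels)
    return fitted, float(scores.mean())
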