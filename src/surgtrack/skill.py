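"""Novice/skilled/expert classification from normalized motion metrics.

Three model families are supported — a linear (multinomial logistic)
classifier, a Gaussian-kernel SVM and a Gini random forest — tuned by
five-fold cross-validated accuracy with SMOTE class balancing applied
inside each training fold only (oversampling before splitting would leak
synthetic copies of validation points into training).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

CLASS_ORDER = ("novice", "skilled", "expert")

DEFAULT_GRIDS = {
    "linear": [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)],
    "svm_rbf": [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)],
    "random_forest": [
        {"n_estimators": n, "max_depth": d}
        for n in (50, 100, 200, 500)
        for d in (2, 3, 5, None)
    ],
}
MAX_TUNING_EVALS = 500  # hyperparameter-search budget cap


# ---------------------------------------------------------------------------
# SMOTE


def smote(
    features: np.ndarray,
    labels: Sequence,
    k_neighbors: int = 5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic minority over-sampling.

    Every class is brought up to the majority count; each synthetic sample
    lies on the segment between a minority sample and one of its k nearest
    same-class neighbours: ``s = x + u * (x_nn - x)``, ``u ~ U(0, 1)``.
    Majority points are never altered.  ``k`` is shrunk (with a warning)
    when a minority class is too small; a single-member class cannot be
    oversampled and raises.
    """
    import warnings

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    out_X, out_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = n_max - cnt
        if need == 0:
            continue
        Xc = X[y == cls]
        if cnt == 1:
            raise ValueError(
                f"class {cls!r} has a single member and cannot be oversampled"
            )
        k = k_neighbors
        if cnt <= k:
            k = cnt - 1
            warnings.warn(
                f"class {cls!r} has {cnt} members; shrinking k_neighbors to {k}"
            )
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        base = rng.integers(0, cnt, size=need)
        pick = rng.integers(1, k + 1, size=need)  # skip self at position 0
        u = rng.random(need)
        x0 = Xc[base]
        x1 = Xc[idx[base, pick]]
        out_X.append(x0 + u[:, None] * (x1 - x0))
        out_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(out_X), np.concatenate(out_y)


# ---------------------------------------------------------------------------
# estimator


def _base_model(kind: str, params: Dict, seed: int):
    if kind == "linear":
        return LogisticRegression(max_iter=2000, **params)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", gamma="scale", probability=True, random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(criterion="gini", random_state=seed, **params)
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "random_forest"
    cv_folds: int = 5
    grid: Optional[List[Dict]] = None
    smote_k: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.kind not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


class SkillClassifier(BaseEstimator, ClassifierMixin):
    """Cross-validation-tuned skill classifier (sklearn estimator API).

    Parameters
    ----------
    kind : {"linear", "svm_rbf", "random_forest"}
    cv_folds : folds for the tuning cross-validation (default 5).
    grid : hyperparameter candidates; defaults per model family, capped at
        500 evaluations.
    smote_k : SMOTE neighbour count applied inside each training fold.
    random_state : seed for SMOTE, fold shuffling and the models.
    """

    def __init__(
        self,
        kind: str = "random_forest",
        cv_folds: int = 5,
        grid: Optional[List[Dict]] = None,
        smote_k: int = 5,
        random_state: int = 0,
    ):
        self.kind = kind
        self.cv_folds = cv_folds
        self.grid = grid
        self.smote_k = smote_k
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        if counts.min() < self.cv_folds:
            raise ValueError(
                f"need >= {self.cv_folds} samples per class for {self.cv_folds}-fold CV"
            )
        grid = self.grid if self.grid is not None else DEFAULT_GRIDS[self.kind]
        grid = list(grid)[:MAX_TUNING_EVALS]
        skf = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(X, y))
        results = []
        for gi, params in enumerate(grid):
            fold_acc = []
            for fi, (tr, va) in enumerate(folds):
                Xb, yb = smote(
                    X[tr], y[tr], k_neighbors=self.smote_k,
                    seed=self.random_state + 997 * fi,
                )
                m = _base_model(self.kind, params, self.random_state)
                m.fit(Xb, yb)
                fold_acc.append(float((m.predict(X[va]) == y[va]).mean()))
            results.append({"params": params, "fold_accuracy": fold_acc,
                            "mean_accuracy": float(np.mean(fold_acc))})
        best = max(range(len(results)), key=lambda i: (results[i]["mean_accuracy"], -i))
        self.best_params_ = dict(results[best]["params"])
        self.cv_report_ = {
            "kind": self.kind,
            "results": results,
            "selected": self.best_params_,
            "cv_accuracy": results[best]["mean_accuracy"],
        }
        Xb, yb = smote(X, y, k_neighbors=self.smote_k, seed=self.random_state)
        self.model_ = _base_model(self.kind, self.best_params_, self.random_state)
        self.model_.fit(Xb, yb)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def predict(self, X):
        return self.model_.predict(self._check_X(X))

    def predict_proba(self, X):
        return self.model_.predict_proba(self._check_X(X))

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())


def train_skill_model(
    features, labels, spec: ModelSpec = ModelSpec()
) -> Tuple[SkillClassifier, Dict]:
    """Fit a tuned model; returns ``(model, cv_report)``."""
    clf = SkillClassifier(
        kind=spec.kind,
        cv_folds=spec.cv_folds,
        grid=spec.grid,
        smote_k=spec.smote_k,
        random_state=spec.seed,
    )
    clf.fit(features, labels)
    return clf, clf.cv_report_


def predict_skill(model: SkillClassifier, features):
    """Labels (and probabilities when available) for new metric vectors."""
    labels = model.predict(features)
    try:
        proba = model.predict_proba(features)
    except Exception:
        proba = None
    return labels, proba


def confusion_matrix_table(y_true, y_pred, classes: Sequence[str] = CLASS_ORDER):
    """Confusion matrix with fixed novice<skilled<expert ordering."""
    from sklearn.metrics import confusion_matrix

    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    return pd.DataFrame(cm, index=list(classes), columns=list(classes))


def feature_importance(
    model: SkillClassifier, feature_names: Sequence[str]
) -> List[Tuple[str, float]]:
    """Mean Gini impurity decrease per feature, normalized, descending."""
    check_is_fitted(model, "model_")
    if not isinstance(model.model_, RandomForestClassifier):
        raise ValueError("feature importance requires a random-forest model")
    imp = np.asarray(model.model_.feature_importances_, dtype=float)
    s = imp.sum()
    if s > 0:
        imp = imp / s
    order = np.argsort(-imp, kind="stable")
    return [(feature_names[i], float(imp[i])) for i in order]


# ---------------------------------------------------------------------------
# persistence: single JSON-based archive with the normalizer embedded


def save_model(model: SkillClassifier, normalizer, path) -> None:
    import pickle
    from pathlib import Path

    blob = pickle.dumps({"model": model, "normalizer": normalizer})
    Path(path).write_bytes(blob)


def load_model(path):
    import pickle
    from pathlib import Path

    doc = pickle.loads(Path(path).read_bytes())
    return doc["model"], doc["normalizer"]
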