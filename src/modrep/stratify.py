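"""Cross-validated feature selection and probabilistic patient stratification.

A regularized logistic model with standardized inputs is the default
classifier (probability outputs, stable at p >> n); a radial-kernel SVM
backend is available.  Backward feature selection repeatedly drops the
feature with the smallest absolute standardized coefficient while
stratified k-fold CV accuracy does not decrease.  Intermediate-group
samples are labeled "pSS-like" when the trained model's class probability
strictly exceeds the confidence threshold (default 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .counts_io import ValidationError

POSITIVE = "pSS"
NEGATIVE = "HC"


@dataclass
class ClassifierSpec:
    features: list[str]
    cv_folds: int = 10
    confidence_threshold: float = 0.75
    backend: str = "logistic"  # or "svm-rbf"
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if not (0.5 < self.confidence_threshold < 1.0):
            raise ValidationError("confidence_threshold must be in (0.5, 1)")


def _make_model(backend: str = "logistic", C: float = 1.0, seed: int = 0) -> Pipeline:
    if backend == "logistic":
        clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    elif backend == "svm-rbf":
        clf = SVC(C=C, kernel="rbf", probability=True, random_state=seed)
    else:
        raise ValidationError(f"unknown backend {backend!r}")
    return make_pipeline(StandardScaler(), clf)


def _design(vsd: pd.DataFrame, features: Sequence[str], samples: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in vsd.index]
    if missing:
        raise ValidationError(f"features missing from matrix: {missing[:10]}")
    return vsd.loc[list(features), list(samples)].to_numpy(dtype=float).T


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, backend: str, C: float
) -> float:
    folds = min(folds, int(np.bincount(y).min()))
    if folds < 2:
        raise ValidationError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(X, y):
        model = _make_model(backend, C, seed)
        model.fit(X[train], y[train])
        correct += int((model.predict(X[test]) == y[test]).sum())
    return correct / len(y)


def select_features(
    vsd: pd.DataFrame,
    labels: pd.Series,
    candidate_genes: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    backend: str = "logistic",
    C: float = 1.0,
    tolerance: float = 0.0,
) -> list[str]:
    """Backward feature elimination under stratified CV accuracy.

    Starting from the full candidate set, the feature with the smallest
    absolute standardized logistic coefficient is dropped as long as CV
    accuracy does not fall below the best accuracy seen so far (minus
    ``tolerance``).  Deterministic for a fixed seed.  A single candidate is
    returned unchanged.
    """
    features = [g for g in dict.fromkeys(candidate_genes)]
    if not features:
        raise ValidationError("empty candidate set")
    samples = list(labels.index)
    y = (labels.loc[samples] == POSITIVE).to_numpy(dtype=int)
    _check_two_classes(y)
    if len(features) == 1:
        return features

    best_acc = _cv_accuracy(_design(vsd, features, samples), y, folds, seed, backend, C)
    while len(features) > 1:
        X = _design(vsd, features, samples)
        ranker = make_pipeline(StandardScaler(), LogisticRegression(C=C, max_iter=2000))
        ranker.fit(X, y)
        coefs = np.abs(ranker[-1].coef_.ravel())
        drop_idx = int(np.argmin(coefs))
        trial = features[:drop_idx] + features[drop_idx + 1 :]
        acc = _cv_accuracy(_design(vsd, trial, samples), y, folds, seed, backend, C)
        if acc + 1e-12 >= best_acc - tolerance:
            features = trial
            best_acc = max(best_acc, acc)
        else:
            break
    return features


def fit_predict_cv(
    vsd: pd.DataFrame,
    labels: pd.Series,
    features: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    backend: str = "logistic",
    C: float = 1.0,
) -> tuple[pd.Series, dict[str, float]]:
    """Out-of-fold class probabilities plus sensitivity/specificity.

    Sensitivity is recall on the positive (pSS) class, specificity on HC,
    both at the 0.5 probability cut.
    """
    samples = list(labels.index)
    y = (labels.loc[samples] == POSITIVE).to_numpy(dtype=int)
    _check_two_classes(y)
    X = _design(vsd, features, samples)
    folds_eff = min(folds, int(np.bincount(y).min()))
    if folds_eff < 2:
        raise ValidationError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    proba = np.full(len(y), np.nan)
    for train, test in skf.split(X, y):
        model = _make_model(backend, C, seed)
        model.fit(X[train], y[train])
        pos_col = int(np.where(model.classes_ == 1)[0][0])
        proba[test] = model.predict_proba(X[test])[:, pos_col]
    pred = (proba > 0.5).astype(int)
    sens = float((pred[y == 1] == 1).mean())
    spec = float((pred[y == 0] == 0).mean())
    acc = float((pred == y).mean())
    return (
        pd.Series(proba, index=samples, name="p_pSS"),
        {"sensitivity": sens, "specificity": spec, "accuracy": acc,
         "folds": float(folds_eff)},
    )


def train_classifier(
    vsd: pd.DataFrame,
    labels: pd.Series,
    features: Sequence[str],
    seed: int = 0,
    backend: str = "logistic",
    C: float = 1.0,
) -> dict:
    """Fit the final model on all pSS/HC samples; returns a model bundle."""
    samples = list(labels.index)
    y = (labels.loc[samples] == POSITIVE).to_numpy(dtype=int)
    _check_two_classes(y)
    X = _design(vsd, features, samples)
    model = _make_model(backend, C, seed)
    model.fit(X, y)
    return {"model": model, "features": list(features)}


def classify_intermediate(
    bundle: dict,
    vsd: pd.DataFrame,
    samples: Sequence[str],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Label intermediate samples pSS-like when P(pSS) strictly exceeds threshold."""
    features = bundle["features"]
    model = bundle["model"]
    X = _design(vsd, features, samples)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    proba = model.predict_proba(X)[:, pos_col]
    label = np.where(proba > threshold, "pSS-like", "reference")
    return pd.DataFrame(
        {"p_pSS": proba, "label": label}, index=pd.Index(list(samples), name="sample_id")
    )
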