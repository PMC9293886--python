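"""Candidate classification: RBF-SVM, MCC metrics, baselines.

Candidates are classified focus / non-focus. Because foci are several
times rarer than background perturbations, performance is measured with
the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which ranges from -1 (perfect misclassification) through 0 (chance) to 1
(perfect classification) and is robust to class imbalance. Generalization
is reported as the mean MCC over a sixfold cross-validation (CVMCC).
Hyperparameters C and gamma of the RBF kernel are tuned by logarithmic
grid search over [1e-3, 1e3] and [1e-8, 10] respectively, maximizing
CVMCC. A random quantifier that matches per-cell selection counts but
picks candidates uniformly at random provides the chance baseline
(mean MCC over 50 repetitions, expected ~0). Datasets with bright,
unambiguous foci can skip training entirely and use per-feature threshold
bounds instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FeatureScaler


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_labels(cls, truth: np.ndarray, pred: np.ndarray) -> "ConfusionMatrix":
        truth = np.asarray(truth).astype(int)
        pred = np.asarray(pred).astype(int)
        if truth.shape != pred.shape:
            raise ValueError("label arrays must have the same shape")
        return cls(
            TP=int(np.sum((truth == 1) & (pred == 1))),
            TN=int(np.sum((truth == 0) & (pred == 0))),
            FP=int(np.sum((truth == 0) & (pred == 1))),
            FN=int(np.sum((truth == 1) & (pred == 0))),
        )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    A zero factor in the denominator yields 0 (the standard convention);
    an all-zero matrix is an error.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    num = cm.TP * cm.TN - cm.FP * cm.FN
    den = (
        (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    if den == 0:
        return 0.0
    return float(num / math.sqrt(den))


def mcc_labels(truth: np.ndarray, pred: np.ndarray) -> float:
    return mcc(ConfusionMatrix.from_labels(truth, pred))


class FocusSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM over whitened, [0, 1]-rescaled focus features.

    A sklearn-compatible estimator: ``fit(X, y)`` fits the feature scaler
    and the SVC on raw (unscaled) feature matrices; ``predict(X)`` applies
    the stored scaler and returns {0, 1} labels. Deterministic given its
    inputs.
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "scale", random_state: int = 0):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FocusSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(
                "training data contains a single class; an SVM needs negative "
                "examples as well — use threshold_classify for unambiguous data"
            )
        self.scaler_ = FeatureScaler().fit(X)
        self.svc_ = SVC(
            C=self.C, gamma=self.gamma, kernel="rbf", random_state=self.random_state
        )
        self.svc_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.svc_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "svc_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features_in_}"
            )
        return self.svc_.predict(self.scaler_.transform(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:  # MCC, not accuracy
        return mcc_labels(y, self.predict(X))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "svc_")
        return {
            "C": self.C,
            "gamma": self.gamma,
            "random_state": self.random_state,
            "scaler": self.scaler_.to_dict(),
            "support_vectors": self.svc_.support_vectors_.tolist(),
            "dual_coef": self.svc_.dual_coef_.tolist(),
            "intercept": self.svc_.intercept_.tolist(),
            "classes": self.svc_.classes_.tolist(),
            "gamma_value": float(self.svc_._gamma),
            "n_features": int(self.n_features_in_),
            "feature_names": FEATURE_NAMES,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "FocusSVC":
        model = cls(C=d["C"], gamma=d["gamma"], random_state=d["random_state"])
        model.scaler_ = FeatureScaler.from_dict(d["scaler"])
        model.n_features_in_ = d["n_features"]
        sv = np.asarray(d["support_vectors"], dtype=float)
        dual = np.asarray(d["dual_coef"], dtype=float)
        b = np.asarray(d["intercept"], dtype=float)
        classes = np.asarray(d["classes"])
        gamma_value = d["gamma_value"]

        class _KernelPredictor:
            classes_ = classes

            def predict(self, X):
                k = np.exp(
                    -gamma_value
                    * ((X[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
                )
                dec = k @ dual[0] + b[0]
                return np.where(dec > 0, classes[1], classes[0])

        model.svc_ = _KernelPredictor()  # type: ignore[assignment]
        model.classes_ = classes
        return model

    @classmethod
    def load(cls, path: str | Path) -> "FocusSVC":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, gamma: float | str = "scale"
) -> FocusSVC:
    """Fit a :class:`FocusSVC` on a labeled feature matrix."""
    return FocusSVC(C=C, gamma=gamma).fit(X, y)


def _stratified_folds(
    y: np.ndarray, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def cv_mcc(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 6,
    C: float = 1.0,
    gamma: float | str = "scale",
    seed: int = 0,
) -> float:
    """Mean MCC over a seeded, label-stratified k-fold cross-validation.

    Each fold's model is trained on the complement and scored on the fold;
    folds are disjoint, cover the dataset and differ in size by at most 1.
    """
    y = np.asarray(y).astype(int)
    if k > len(y):
        raise ValueError("more folds than samples")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            "every fold must contain both classes; reduce k or relabel"
        )
    scores = []
    for train_idx, test_idx in _stratified_folds(y, k, seed):
        model = FocusSVC(C=C, gamma=gamma).fit(X[train_idx], y[train_idx])
        scores.append(mcc_labels(y[test_idx], model.predict(X[test_idx])))
    return float(np.mean(scores))


def default_grids() -> tuple[np.ndarray, np.ndarray]:
    """Logarithmic C in [1e-3, 1e3] and gamma in [1e-8, 10] grids."""
    return np.logspace(-3, 3, 7), np.logspace(-8, 1, 10)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: np.ndarray | None = None,
    gamma_grid: np.ndarray | None = None,
    k: int = 6,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Pick (C, gamma) maximizing CVMCC; ties prefer smaller C, then gamma.

    Grid points where training fails are skipped. Returns
    ``(C, gamma, best_cvmcc)``.
    """
    if C_grid is None or gamma_grid is None:
        dC, dg = default_grids()
        C_grid = dC if C_grid is None else C_grid
        gamma_grid = dg if gamma_grid is None else gamma_grid
    best: tuple[float, float, float] | None = None
    for C in sorted(float(c) for c in C_grid):
        for gamma in sorted(float(g) for g in gamma_grid):
            try:
                score = cv_mcc(X, y, k=k, C=C, gamma=gamma, seed=seed)
            except Exception:
                continue  # skip grid points whose models cannot be trained
            if best is None or score > best[2] + 1e-12:
                best = (C, gamma, score)
    if best is None:
        raise RuntimeError("no grid point could be trained")
    return best


def random_quantifier(
    reference: list[np.ndarray],
    n_reps: int = 50,
    seed: int = 0,
) -> float:
    """Chance baseline: per cell, pick as many candidates as the reference
    did, uniformly at random without replacement; pool all cells, score the
    MCC against the reference, and average over ``n_reps`` repetitions.

    ``reference`` holds one binary selection array per cell. Repetitions in
    which either pooled labeling is single-class score 0 by the MCC
    zero-denominator convention.
    """
    rng = np.random.default_rng(seed)
    ref_pooled = np.concatenate([np.asarray(r).astype(int) for r in reference])
    scores = []
    for _ in range(n_reps):
        picks = []
        for r in reference:
            r = np.asarray(r).astype(int)
            chosen = rng.choice(len(r), size=int(r.sum()), replace=False)
            sel = np.zeros(len(r), dtype=int)
            sel[chosen] = 1
            picks.append(sel)
        scores.append(mcc_labels(ref_pooled, np.concatenate(picks)))
    return float(np.mean(scores))


def threshold_classify(
    X: np.ndarray,
    bounds: dict[str, tuple[float | None, float | None]],
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """Parameterless-training pipeline: label 1 iff every bounded feature
    lies inside its [lo, hi] interval (None = unbounded side)."""
    X = np.asarray(X, dtype=float)
    names = feature_names or FEATURE_NAMES
    labels = np.ones(len(X), dtype=int)
    for name, (lo, hi) in bounds.items():
        if name not in names:
            raise KeyError(f"unknown feature {name!r}")
        if lo is not None and hi is not None and lo > hi:
            raise ValueError(f"bounds for {name!r} have lo > hi")
        col = X[:, names.index(name)]
        if lo is not None:
            labels &= col >= lo
        if hi is not None:
            labels &= col <= hi
    return labels


def predict(
    model: FocusSVC,
    X: np.ndarray,
    cell_ids: np.ndarray | None = None,
    overrides: dict[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Apply a trained model; manual corrections override after prediction.

    ``overrides`` maps candidate index -> forced label. Returns the labels
    and a per-cell summary {cell id: number of positive candidates}.
    """
    labels = model.predict(X).astype(int)
    if overrides:
        for idx, lab in overrides.items():
            labels[idx] = int(lab)
    summary: dict = {}
    if cell_ids is not None:
        cell_ids = np.asarray(cell_ids)
        for cid in np.unique(cell_ids):
            summary[cid.item() if hasattr(cid, "item") else cid] = int(
                labels[cell_ids == cid].sum()
            )
    return labels, summary
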