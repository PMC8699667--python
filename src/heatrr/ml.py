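"""Classification layer: SVM / CNN / threshold models with a repeated
stratified 10-fold cross-validation harness.

AFib is the positive class throughout (sensitivity = AFib recall,
specificity = AFlu recall).  Standardisation parameters and
hyperparameters are learned on training folds only: the harness runs an
inner grid-search cross-validation nested inside every outer training
fold, so no information from a test fold ever reaches model selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import CNNConfig, NumpyCNN

__all__ = [
    "HyperParamGrid",
    "CVResult",
    "ThresholdClassifier",
    "train_svm",
    "train_cnn",
    "evaluate",
    "cross_validate",
]

POSITIVE_LABEL = 1  # AFib


@dataclass(frozen=True)
class HyperParamGrid:
    """Hyperparameter search space for the SVM and CNN models.

    The SVM grid spans the kernel type, penalty ``C`` and kernel
    coefficient ``gamma`` (3 values each by default) and the window
    length ``n_sub``; the CNN tunes the dropout rate and ``n_sub``.
    """

    kernels: tuple[str, ...] = ("rbf", "poly")
    C: tuple[float, ...] = (0.1, 1.0, 10.0)
    gamma: tuple[float, ...] = (0.01, 0.1, 1.0)
    n_sub: Optional[tuple[int, ...]] = None
    dropout: tuple[float, ...] = (0.1, 0.2, 0.3)

    def __post_init__(self) -> None:
        if not (self.kernels and self.C and self.gamma and self.dropout):
            raise ValueError("hyperparameter grids must be non-empty")

    def svm_configurations(
        self, n_sub_values: Sequence[int]
    ) -> list[dict]:
        return [
            {"kernel": k, "C": c, "gamma": g, "n_sub": ns}
            for k, c, g, ns in itertools.product(
                self.kernels, self.C, self.gamma, n_sub_values
            )
        ]


@dataclass
class CVResult:
    """Per-fold and aggregate performance under repeated stratified CV."""

    per_fold: pd.DataFrame  # columns: repeat, fold, accuracy, roc_area
    mean_accuracy: float
    sd_accuracy: float
    mean_roc: float
    sd_roc: float
    sensitivity: float
    specificity: float
    chosen_hyperparameters: dict

    def summary(self) -> str:
        return (
            f"accuracy {100 * self.mean_accuracy:.2f}% "
            f"± {100 * self.sd_accuracy:.2f}%, "
            f"ROC area {self.mean_roc:.2f} ± {self.sd_roc:.2f}, "
            f"sensitivity {100 * self.sensitivity:.2f}%, "
            f"specificity {100 * self.specificity:.2f}%"
        )


class ThresholdClassifier:
    """One-dimensional threshold rule on a single feature.

    The decision score is the feature value itself (optionally sign
    flipped so the positive class scores higher on the training data);
    the cut maximising training accuracy, taken midway between adjacent
    distinct values, is the decision threshold.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThresholdClassifier":
        x = np.asarray(X, dtype=float).reshape(len(y))
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to fit")
        self.flip = 1.0
        if x[y == POSITIVE_LABEL].mean() < x[y != POSITIVE_LABEL].mean():
            self.flip = -1.0
        s = self.flip * x
        candidates = np.unique(s)
        cuts = np.concatenate(
            [[candidates[0] - 1.0], (candidates[:-1] + candidates[1:]) / 2.0,
             [candidates[-1] + 1.0]]
        )
        best_acc, best_cut = -1.0, cuts[0]
        for cut in cuts:
            acc = np.mean((s > cut).astype(int) == (y == POSITIVE_LABEL))
            if acc > best_acc:
                best_acc, best_cut = acc, cut
        self.threshold = float(best_cut)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.flip * x - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Optional[dict] = None,
) -> Pipeline:
    """Fit a standardised SVM with a continuous decision score.

    The standardiser is part of the returned pipeline, so its parameters
    are always learned from whatever data ``fit`` saw — never from
    evaluation data.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    hp = hyperparams or {}
    model = Pipeline(
        [
            ("standardize", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=hp.get("kernel", "rbf"),
                    C=hp.get("C", 1.0),
                    gamma=hp.get("gamma", "scale"),
                    random_state=0,
                ),
            ),
        ]
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def train_cnn(
    windows: np.ndarray,
    y: np.ndarray,
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> NumpyCNN:
    """Fit the convolutional baseline on fixed-length RR windows."""
    hp = hyperparams or {}
    cfg = CNNConfig(
        dropout=hp.get("dropout", 0.2),
        epochs=hp.get("epochs", 200),
        batch_size=hp.get("batch_size", 32),
    )
    return NumpyCNN(cfg, seed=seed).fit(np.asarray(windows, dtype=float), y)


def evaluate(
    classifier, X: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, ROC area, sensitivity, specificity) on labelled data.

    The ROC area is computed from the classifier's continuous decision
    scores by the trapezoidal rank method; sensitivity is AFib recall and
    specificity AFlu recall.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: only one class present")
    pred = np.asarray(classifier.predict(X)).astype(int)
    scores = np.asarray(classifier.decision_function(X), dtype=float)
    acc = float(np.mean(pred == y))
    roc = float(roc_auc_score((y == POSITIVE_LABEL).astype(int), scores))
    pos = y == POSITIVE_LABEL
    sens = float(np.mean(pred[pos] == POSITIVE_LABEL)) if pos.any() else np.nan
    spec = float(np.mean(pred[~pos] != POSITIVE_LABEL)) if (~pos).any() else np.nan
    return acc, roc, sens, spec


FeatureData = Union[np.ndarray, Mapping[int, np.ndarray]]


def _resolve_X(dataset: FeatureData, n_sub: Optional[int]) -> np.ndarray:
    if isinstance(dataset, Mapping):
        if n_sub is None:
            raise ValueError("n_sub required for a per-window feature mapping")
        return np.asarray(dataset[n_sub], dtype=float)
    return np.asarray(dataset, dtype=float)


def _fit_model(model_spec: str, X, y, hp: dict, seed: int):
    if model_spec == "svm":
        return train_svm(X, y, hp)
    if model_spec == "cnn":
        return train_cnn(X, y, hp, seed=seed)
    if model_spec == "threshold":
        return ThresholdClassifier().fit(X, y)
    raise ValueError(f"unknown model_spec {model_spec!r}")


def _grid_for(model_spec: str, grid: HyperParamGrid,
              n_sub_values: list) -> list[dict]:
    if model_spec == "svm":
        return [
            {**hp}
            for hp in grid.svm_configurations(n_sub_values)
        ]
    if model_spec == "cnn":
        return [
            {"dropout": d, "n_sub": ns}
            for d, ns in itertools.product(grid.dropout, n_sub_values)
        ]
    return [{"n_sub": n_sub_values[0]}]  # threshold model has no grid


def cross_validate(
    dataset: FeatureData,
    y: np.ndarray,
    model_spec: str = "svm",
    grid: Optional[HyperParamGrid] = None,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    inner_folds: int = 3,
) -> CVResult:
    """Repeated stratified k-fold cross-validation with nested tuning.

    ``dataset`` is either a feature matrix or a mapping
    ``n_sub -> feature matrix`` (rows aligned with ``y``) when the window
    length is part of the hyperparameter grid.  For every outer training
    fold, hyperparameters are selected by an inner stratified grid-search
    CV (mean accuracy, first-in-grid tie-break), the model is refit on
    the full training fold and scored on the held-out fold.  Sensitivity
    and specificity pool the held-out predictions over all folds and
    repeats at the default decision threshold.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    grid = grid or HyperParamGrid()
    if isinstance(dataset, Mapping):
        n_sub_values = sorted(dataset) if grid.n_sub is None else list(grid.n_sub)
    else:
        n_sub_values = [None]
    configurations = _grid_for(model_spec, grid, n_sub_values)

    outer = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    n = len(y)
    rows = []
    chosen: list[tuple] = []
    tp = tn = fp = fn = 0
    for split_i, (tr, te) in enumerate(outer.split(np.zeros(n), y)):
        if len(configurations) > 1:
            hp = _select_hyperparameters(
                dataset, y, tr, model_spec, configurations, inner_folds, seed
            )
        else:
            hp = configurations[0]
        X = _resolve_X(dataset, hp.get("n_sub"))
        model = _fit_model(model_spec, X[tr], y[tr], hp, seed)
        acc, roc, _, _ = evaluate(model, X[te], y[te])
        pred = np.asarray(model.predict(X[te])).astype(int)
        pos = y[te] == POSITIVE_LABEL
        tp += int(np.sum(pred[pos] == POSITIVE_LABEL))
        fn += int(np.sum(pred[pos] != POSITIVE_LABEL))
        tn += int(np.sum(pred[~pos] != POSITIVE_LABEL))
        fp += int(np.sum(pred[~pos] == POSITIVE_LABEL))
        rows.append(
            {
                "repeat": split_i // folds,
                "fold": split_i % folds,
                "accuracy": acc,
                "roc_area": roc,
            }
        )
        chosen.append(tuple(sorted(hp.items(), key=lambda kv: kv[0])))
    per_fold = pd.DataFrame(rows)
    counts: dict = {}
    for c in chosen:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts, key=lambda c: (counts[c],))
    return CVResult(
        per_fold=per_fold,
        mean_accuracy=float(per_fold["accuracy"].mean()),
        sd_accuracy=float(per_fold["accuracy"].std(ddof=1)),
        mean_roc=float(per_fold["roc_area"].mean()),
        sd_roc=float(per_fold["roc_area"].std(ddof=1)),
        sensitivity=tp / (tp + fn) if (tp + fn) else math.nan,
        specificity=tn / (tn + fp) if (tn + fp) else math.nan,
        chosen_hyperparameters=dict(best),
    )


def _select_hyperparameters(
    dataset: FeatureData,
    y: np.ndarray,
    train_idx: np.ndarray,
    model_spec: str,
    configurations: list[dict],
    inner_folds: int,
    seed: int,
) -> dict:
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                            random_state=seed)
    y_tr = y[train_idx]
    best_score, best_hp = -np.inf, configurations[0]
    for hp in configurations:
        X = _resolve_X(dataset, hp.get("n_sub"))[train_idx]
        scores = []
        for itr, ite in inner.split(X, y_tr):
            model = _fit_model(model_spec, X[itr], y_tr[itr], hp, seed)
            pred = np.asarray(model.predict(X[ite])).astype(int)
            scores.append(float(np.mean(pred == y_tr[ite])))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first-in-grid wins ties
            best_score, best_hp = score, hp
    return best_hp
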