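"""Elastic-net penalized logistic regression on pathway activity features.

Training follows a nested protocol: an outer repeated stratified K-fold loop
estimates held-out AUC-ROC / AUC-PR, while hyperparameters (l1 ratio and
inverse regularization strength C) are chosen by a grid search run inside
each outer training split, so the reported performance never sees the tuning
data. The deployed model is refit on all samples with the hyperparameter
pair selected most often across outer folds (ties broken toward stronger
regularization, i.e. smaller C, then larger l1 ratio).

Features are standardized (mean 0, variance 1 per pathway) inside each
training split; the final scaler is stored with the model and reapplied at
prediction time so calibrated scores are transformed coherently.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .data_io import DISEASE, HEALTHY
from .ssgsea import PathwayActivityMatrix

ARTIFACT_VERSION = 1

DEFAULT_GRID = {
    "l1_ratio": [0.1, 0.3, 0.5, 0.7, 0.9],
    "C": list(np.logspace(-3, 2, 6)),
}


class TrainingError(ValueError):
    pass


@dataclass
class TrainedClassifier:
    """Fitted coefficients plus the metadata needed to reapply the model."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    hyperparams: dict
    cv_summary: dict
    seed: int
    refit_on_all: bool = True
    version: int = ARTIFACT_VERSION

    # -- prediction --------------------------------------------------------

    def decision_function(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.index) != self.feature_names:
            raise ValueError("feature names/order do not match the model")
        z = (features.to_numpy().T - self.scaler_mean) / self.scaler_scale
        return z @ self.coef + self.intercept

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """P(disease) per sample (columns of ``features``)."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(features)))

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "feature_names": self.feature_names,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "hyperparams": self.hyperparams,
            "cv_summary": self.cv_summary,
            "seed": self.seed,
            "refit_on_all": self.refit_on_all,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        d = json.loads(Path(path).read_text())
        return cls(feature_names=d["feature_names"],
                   coef=np.asarray(d["coef"], dtype=float),
                   intercept=float(d["intercept"]),
                   scaler_mean=np.asarray(d["scaler_mean"], dtype=float),
                   scaler_scale=np.asarray(d["scaler_scale"], dtype=float),
                   hyperparams=d["hyperparams"], cv_summary=d["cv_summary"],
                   seed=int(d["seed"]), refit_on_all=bool(d["refit_on_all"]),
                   version=int(d["version"]))


def _make_pipeline(seed: int) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("logit", LogisticRegression(solver="saga", l1_ratio=0.5,
                                     max_iter=5000, tol=1e-4,
                                     random_state=seed)),
    ])


def train(pas: PathwayActivityMatrix,
          grid: dict | None = None,
          repeats: int = 10,
          folds: int = 10,
          seed: int = 0,
          inner_folds: int = 3) -> TrainedClassifier:
    """Nested repeated stratified CV with grid search in the inner loop.

    Raises :class:`TrainingError` when only one class is present or when
    ``folds`` exceeds the minority class size.
    """
    X = pas.scores.to_numpy().T
    if not np.isfinite(X).all():
        raise TrainingError("non-finite pathway features")
    y = np.asarray([1 if pas.labels[s] == DISEASE else 0 for s in pas.sample_ids])
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes required for training")
    minority = min(np.bincount(y))
    if folds > minority:
        raise TrainingError(
            f"folds={folds} exceeds minority class size {minority}")

    grid = dict(grid or DEFAULT_GRID)
    param_grid = {"logit__l1_ratio": grid["l1_ratio"], "logit__C": grid["C"]}
    outer = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                    random_state=seed)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)

    chosen: Counter = Counter()
    aucs_roc, aucs_pr = [], []
    with warnings.catch_warnings():
        # weakly-regularized grid corners on separable data hit max_iter;
        # they never win the selection, so the warning is pure noise here
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for tr, te in outer.split(X, y):
            gs = GridSearchCV(_make_pipeline(seed), param_grid, cv=inner,
                              scoring="roc_auc", n_jobs=None)
            gs.fit(X[tr], y[tr])
            pair = (float(gs.best_params_["logit__l1_ratio"]),
                    float(gs.best_params_["logit__C"]))
            chosen[pair] += 1
            prob = gs.predict_proba(X[te])[:, 1]
            aucs_roc.append(roc_auc_score(y[te], prob))
            aucs_pr.append(average_precision_score(y[te], prob))

    # modal pair; ties -> stronger regularization (smaller C), sparser (larger l1)
    best = max(chosen.items(), key=lambda kv: (kv[1], -kv[0][1], kv[0][0]))[0]
    l1_ratio, C = best

    final = _make_pipeline(seed)
    final.set_params(logit__l1_ratio=l1_ratio, logit__C=C)
    final.fit(X, y)
    scaler: StandardScaler = final.named_steps["scale"]
    logit: LogisticRegression = final.named_steps["logit"]

    return TrainedClassifier(
        feature_names=pas.pathway_ids,
        coef=logit.coef_.ravel().copy(),
        intercept=float(logit.intercept_[0]),
        scaler_mean=scaler.mean_.copy(),
        scaler_scale=scaler.scale_.copy(),
        hyperparams={"l1_ratio": l1_ratio, "C": C,
                     "selection_counts": {f"{k[0]}/{k[1]:g}": v
                                          for k, v in sorted(chosen.items())}},
        cv_summary={"auc_roc_mean": float(np.mean(aucs_roc)),
                    "auc_pr_mean": float(np.mean(aucs_pr)),
                    "auc_roc": [float(a) for a in aucs_roc],
                    "auc_pr": [float(a) for a in aucs_pr],
                    "repeats": repeats, "folds": folds},
        seed=seed)


def predict_labels(model: TrainedClassifier,
                   features: pd.DataFrame) -> pd.Series:
    """Per-sample class label at the fixed 0.5 probability threshold.

    ``features`` is a pathways x samples frame whose row order must match the
    model's feature ordering.
    """
    prob = model.predict_proba(features)
    labels = np.where(prob > 0.5, DISEASE, HEALTHY)
    return pd.Series(labels, index=features.columns)
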