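"""Event classification from the three blockade features.

Each detected event is characterised by its residual level (ires %), its
duration, and its within-event RMS noise.  Duration and RMS are positive and
right-skewed (durations are exponential), so both are log-transformed before
model fitting.

Two classifier kinds are provided behind one surface:

* ``"gaussian"`` — a self-contained per-class Gaussian baseline: one mean and
  full covariance per class over the three (transformed) features, maximum
  posterior under equal class priors.  Fully specified here, serialises to
  JSON, and is the reference against which the brute-force density oracle is
  checked in the tests.
* ``"forest"`` — a random-forest ensemble (scikit-learn) mirroring the model
  used for multi-aldehyde identification; used for the headline accuracy.

Both follow scikit-learn estimator conventions (``fit``/``predict``,
``classes_`` and other trailing-underscore fitted attributes) and compose
with sklearn model selection.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .analytes import AnalyteSpec, PoreSpec, ValidationError

__all__ = [
    "FEATURES",
    "feature_matrix",
    "stratified_split",
    "GaussianEventClassifier",
    "ClassifierModel",
    "train",
    "evaluate",
    "ConfusionMatrix",
    "train_reference_classifier",
]

FEATURES = ["ires_pct", "duration_s", "rms_noise_pa"]


def feature_matrix(events: pd.DataFrame) -> np.ndarray:
    """(n, 3) design matrix: ires%, log duration, log RMS noise."""
    missing = [c for c in FEATURES if c not in events.columns]
    if missing:
        raise ValidationError(f"events lack feature columns {missing}")
    sub = events[FEATURES]
    if sub.isna().any().any():
        raise ValidationError(
            "events with undefined features present; drop flagged events "
            "before classification")
    x = sub.to_numpy(dtype=float).copy()
    x[:, 1] = np.log(x[:, 1])
    x[:, 2] = np.log(x[:, 2])
    return x


def stratified_split(
    events: pd.DataFrame,
    test_fraction: float = 0.3,
    seed: int = 0,
    label_column: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split; test proportion within one event per class."""
    if not (0.0 <= test_fraction < 1.0):
        raise ValidationError("test_fraction must be in [0, 1)")
    labels = events[label_column]
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValidationError(
            f"classes with a single event cannot be split: {bad}")
    if test_fraction == 0.0:
        return events.copy(), events.iloc[0:0].copy()
    train_df, test_df = train_test_split(
        events, test_size=test_fraction, stratify=labels, random_state=seed)
    return (train_df.reset_index(drop=True),
            test_df.reset_index(drop=True))


class GaussianEventClassifier(ClassifierMixin, BaseEstimator):
    """Per-class Gaussian density classifier with equal priors.

    Fitted attributes: ``classes_``, ``means_`` (k, d) and ``covariances_``
    (k, d, d).  A singular class covariance falls back to its diagonal with a
    warning.
    """

    def __init__(self, reg: float = 1e-9):
        self.reg = reg

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValidationError("X must be 2-D and aligned with y")
        self.classes_, idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValidationError("need >= 2 classes to train")
        d = X.shape[1]
        self.means_ = np.empty((self.classes_.size, d))
        self.covariances_ = np.empty((self.classes_.size, d, d))
        for k in range(self.classes_.size):
            rows = X[idx == k]
            self.means_[k] = rows.mean(axis=0)
            cov = np.cov(rows, rowvar=False)
            cov = np.atleast_2d(cov) + self.reg * np.eye(d)
            cond = np.linalg.cond(cov)
            if not np.isfinite(cond) or cond > 1e12:
                warnings.warn(
                    f"singular covariance for class {self.classes_[k]!r}; "
                    "falling back to its diagonal", stacklevel=2)
                cov = np.diag(np.diag(cov))
            self.covariances_[k] = cov
        return self

    def _log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        out = np.empty((n, self.classes_.size))
        for k in range(self.classes_.size):
            cov = self.covariances_[k]
            sign, logdet = np.linalg.slogdet(cov)
            diff = X - self.means_[k]
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.einsum("ij,ij->i", diff, sol)
            out[:, k] = -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))
        return out

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self.classes_[np.argmax(self._log_likelihood(X), axis=1)]

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        ll = self._log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)


@dataclass
class ClassifierModel:
    """A trained classifier plus its training metadata."""

    kind: str  # "gaussian" | "forest"
    estimator: object
    classes: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def predict(self, events: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(feature_matrix(events))

    def save(self, path: str | Path) -> None:
        """JSON for the Gaussian baseline; a pickle sidecar for the forest."""
        path = Path(path)
        if self.kind == "gaussian":
            est = self.estimator
            doc = {
                "kind": self.kind,
                "classes": list(self.classes),
                "metadata": self.metadata,
                "means": est.means_.tolist(),
                "covariances": est.covariances_.tolist(),
                "reg": est.reg,
            }
            path.write_text(json.dumps(doc, indent=1))
        else:
            sidecar = path.with_suffix(path.suffix + ".pkl")
            doc = {"kind": self.kind, "classes": list(self.classes),
                   "metadata": self.metadata, "sidecar": sidecar.name}
            path.write_text(json.dumps(doc, indent=1))
            with open(sidecar, "wb") as fh:
                pickle.dump(self.estimator, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        path = Path(path)
        doc = json.loads(path.read_text())
        if doc["kind"] == "gaussian":
            est = GaussianEventClassifier(reg=doc.get("reg", 1e-9))
            est.classes_ = np.asarray(doc["classes"])
            est.means_ = np.asarray(doc["means"], dtype=float)
            est.covariances_ = np.asarray(doc["covariances"], dtype=float)
        else:
            with open(path.parent / doc["sidecar"], "rb") as fh:
                est = pickle.load(fh)
        return cls(kind=doc["kind"], estimator=est,
                   classes=tuple(doc["classes"]),
                   metadata=doc.get("metadata", {}))


def train(events: pd.DataFrame, kind: str = "forest", seed: int = 0,
          label_column: str = "label", **estimator_kwargs) -> ClassifierModel:
    """Fit a classifier on a labeled event set."""
    y = events[label_column].to_numpy()
    X = feature_matrix(events)
    if kind == "gaussian":
        est = GaussianEventClassifier(**estimator_kwargs).fit(X, y)
    elif kind == "forest":
        params = {"n_estimators": 300, "random_state": seed}
        params.update(estimator_kwargs)
        est = RandomForestClassifier(**params).fit(X, y)
    else:
        raise ValidationError(f"unknown classifier kind {kind!r}")
    classes = tuple(str(c) for c in np.unique(y))
    return ClassifierModel(kind=kind, estimator=est, classes=classes,
                           metadata={"seed": seed, "n_train": len(events)})


@dataclass
class ConfusionMatrix:
    counts: pd.DataFrame  # rows = true class, columns = predicted class

    @property
    def accuracy(self) -> float:
        total = self.counts.to_numpy().sum()
        if total == 0:
            return float("nan")
        return float(np.trace(self.counts.to_numpy())) / float(total)

    @property
    def per_class_recall(self) -> pd.Series:
        mat = self.counts.to_numpy()
        totals = mat.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rec = np.diag(mat) / totals
        return pd.Series(rec, index=self.counts.index, name="recall")


def evaluate(model: ClassifierModel, test: pd.DataFrame,
             label_column: str = "label") -> ConfusionMatrix:
    """Confusion matrix of a trained model on a labeled test set."""
    classes = list(model.classes)
    if test.empty:
        empty = pd.DataFrame(0, index=classes, columns=classes)
        return ConfusionMatrix(counts=empty)
    unseen = set(test[label_column].astype(str)) - set(classes)
    if unseen:
        raise ValidationError(
            f"test set contains classes unseen in training: {sorted(unseen)}")
    pred = model.predict(test).astype(str)
    true = test[label_column].astype(str).to_numpy()
    counts = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(true, pred):
        counts.loc[t, p] += 1
    return ConfusionMatrix(counts=counts)


def train_reference_classifier(
    analytes: Sequence[AnalyteSpec],
    pore: PoreSpec,
    seed: int = 0,
    kind: str = "gaussian",
    n_per_class: int = 500,
    dead_time: float = 5e-4,
) -> ClassifierModel:
    """Train a classifier on events sampled from fixture parameters.

    This is the calibration route used to label mixture recordings: events
    are drawn per analyte from its configured levels, kinetics and noise.
    """
    from .simulate import sample_labeled_events

    events = sample_labeled_events(list(analytes), n_per_class, pore,
                                   seed=seed, dead_time=dead_time)
    return train(events, kind=kind, seed=seed)
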