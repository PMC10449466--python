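"""Benchmark regressors under a uniform fit/predict contract.

Six families are provided — KNN, random forest, ridge, linear-kernel SVR,
gradient-boosted trees, and a naive-Bayes regressor — each described by a
:class:`RegressorSpec` and trained via :func:`fit` into an immutable
:class:`FittedRegressor`. Defaults follow the study configuration: SVR
linear kernel with C=100, random forest with 20 trees and seed 42, ridge
alpha=0.01, boosting learning rate 0.05.

Standard families delegate to scikit-learn. The naive-Bayes regressor is a
discretize-then-classify construction: the continuous target is binned
(quantile bins by default), a Gaussian NB classifier is fitted over the
bins, and the prediction is the posterior-weighted mean of the per-bin
target means.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

__all__ = [
    "FAMILIES",
    "RegressorSpec",
    "FittedRegressor",
    "NaiveBayesRegressor",
    "fit",
    "predict",
    "make_paper_defaults",
    "nb_regress_fit",
    "save_model",
    "load_model",
]

FAMILIES = ("knn", "rf", "ridge", "svr", "nb", "gbdt")


@dataclass(frozen=True)
class RegressorSpec:
    """A model family plus hyperparameters and an optional seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        h = self.hyperparameters
        checks = {
            "knn": ("k", lambda v: v >= 1, "k >= 1"),
            "ridge": ("alpha", lambda v: v > 0, "alpha > 0"),
            "rf": ("n_trees", lambda v: v >= 1, "n_trees >= 1"),
            "svr": ("C", lambda v: v > 0, "C > 0"),
            "nb": ("n_bins", lambda v: v >= 2, "n_bins >= 2"),
            "gbdt": ("learning_rate", lambda v: 0 < v <= 1, "learning rate in (0, 1]"),
        }
        name, ok, rule = checks[self.family]
        if name in h and not ok(h[name]):
            raise ValueError(f"{self.family}: hyperparameter violates {rule}")


class NaiveBayesRegressor:
    """Gaussian NB over a discretized target, predicting the posterior mean.

    The target is cut into ``n_bins`` bins (``"quantile"`` uses empirical
    quantile edges and requires at least ``n_bins`` distinct target values;
    ``"equal_width"`` uses uniform edges over the target range). A Gaussian
    NB classifier with prior = bin frequency models P(bin | x); the
    prediction is sum_b P(b|x) * mean(y in bin b).
    """

    def __init__(self, n_bins: int = 20, binning: str = "quantile"):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if binning not in ("quantile", "equal_width"):
            raise ValueError(f"unknown binning {binning!r}")
        self.n_bins = n_bins
        self.binning = binning

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NaiveBayesRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.binning == "quantile":
            if np.unique(y).size < self.n_bins:
                raise ValueError(
                    f"quantile binning needs >= {self.n_bins} distinct target values"
                )
            edges = np.quantile(y, np.linspace(0, 1, self.n_bins + 1))
            edges = np.unique(edges)
        else:
            lo, hi = float(y.min()), float(y.max())
            if hi == lo:
                raise ValueError("constant target cannot be binned")
            edges = np.linspace(lo, hi, self.n_bins + 1)
        labels = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(edges) - 2)
        present = np.unique(labels)
        remap = {b: i for i, b in enumerate(present)}
        labels = np.array([remap[b] for b in labels])
        self._bin_means_ = np.array([y[labels == i].mean() for i in range(len(present))])
        self._clf_ = GaussianNB().fit(X, labels)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self._clf_.predict_proba(np.asarray(X, dtype=float))
        return proba @ self._bin_means_


def _build_estimator(spec: RegressorSpec):
    h = spec.hyperparameters
    if spec.family == "knn":
        return KNeighborsRegressor(n_neighbors=int(h.get("k", 5)))
    if spec.family == "rf":
        return RandomForestRegressor(
            n_estimators=int(h.get("n_trees", 20)),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "ridge":
        return Ridge(alpha=float(h.get("alpha", 0.01)))
    if spec.family == "svr":
        # gamma is irrelevant under the linear kernel and ignored
        return SVR(kernel="linear", C=float(h.get("C", 100.0)))
    if spec.family == "gbdt":
        return GradientBoostingRegressor(
            learning_rate=float(h.get("learning_rate", 0.05)),
            random_state=spec.seed,
        )
    if spec.family == "nb":
        return NaiveBayesRegressor(
            n_bins=int(h.get("n_bins", 20)),
            binning=str(h.get("binning", "quantile")),
        )
    raise AssertionError(spec.family)


@dataclass
class FittedRegressor:
    """A fitted model: the spec, the opaque backend, and the feature count."""

    spec: RegressorSpec
    estimator: Any
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected ({'n'}, {self.n_features}) feature matrix, got {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        out = np.asarray(self.estimator.predict(X), dtype=float)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite prediction")
        return out


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"row mismatch: X has {X.shape[0]} rows, y has {y.shape[0]}")
    if X.shape[0] < 1:
        raise ValueError("need at least one training row")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in training data; impute first")
    return X, y


def fit(spec: RegressorSpec, X: np.ndarray, y: np.ndarray) -> FittedRegressor:
    """Fit a model of the given spec. Deterministic given (spec, X, y, seed)."""
    X, y = _check_xy(X, y)
    est = _build_estimator(spec).fit(X, y)
    return FittedRegressor(spec=spec, estimator=est, n_features=X.shape[1])


def predict(model: FittedRegressor, X: np.ndarray) -> np.ndarray:
    """One finite prediction per row of ``X``."""
    return model.predict(X)


def nb_regress_fit(
    X: np.ndarray, y: np.ndarray, n_bins: int = 20, binning: str = "quantile"
) -> FittedRegressor:
    """Fit the discretize-then-classify NB regressor directly."""
    spec = RegressorSpec("nb", {"n_bins": n_bins, "binning": binning})
    return fit(spec, X, y)


def make_paper_defaults() -> dict[str, RegressorSpec]:
    """The study's benchmark hyperparameters, one spec per family."""
    return {
        "svr": RegressorSpec("svr", {"C": 100.0}),
        "nb": RegressorSpec("nb", {"n_bins": 20, "binning": "quantile"}),
        "rf": RegressorSpec("rf", {"n_trees": 20}, seed=42),
        "ridge": RegressorSpec("ridge", {"alpha": 0.01}),
        "gbdt": RegressorSpec("gbdt", {"learning_rate": 0.05}, seed=42),
        "knn": RegressorSpec("knn", {"k": 5}),
    }


def save_model(model: Any, path: str | Path) -> None:
    """Persist a fitted model (or ensemble) to a single file."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> Any:
    with open(path, "rb") as fh:
        return pickle.load(fh)
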