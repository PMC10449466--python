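"""Regression metrics and the multi-phase, multi-trial evaluation protocol.

Four metrics score each (model, phase, trial) cell: MAE, MSE, RMSE and R².
The experiment protocol re-splits the dataset in three phases of
train:test ratio — 80:20, 50:50 and 30:70 — with ten independently seeded
trials per phase, and averages per phase and pooled. Trials differ only in
the split seed (base seed + trial index); model seeds stay at their spec
values so the trial-to-trial spread isolates split variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blend import BlendConfig, fit_krr, predict_krr
from .models import RegressorSpec, fit as fit_model
from .schema import CropDataset

__all__ = [
    "mae",
    "mse",
    "rmse",
    "r2",
    "score_all",
    "split",
    "split_indices",
    "PhaseSpec",
    "MetricsReport",
    "run_experiment",
    "collect_test_errors",
    "DEFAULT_PHASES",
]

METRIC_NAMES = ("mae", "mse", "rmse", "r2")


def _check_pair(y: np.ndarray, yhat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values")
    return y, yhat


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error, 1/n * sum |y - yhat|."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean squared error, 1/n * sum (y - yhat)^2."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean((y - yhat) ** 2))


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, sqrt(mse)."""
    return math.sqrt(mse(y, yhat))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y, yhat = _check_pair(y, yhat)
    if y.size < 2:
        raise ValueError("r2 needs at least 2 points")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def score_all(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    return {"mae": mae(y, yhat), "mse": mse(y, yhat), "rmse": rmse(y, yhat), "r2": r2(y, yhat)}


def split_indices(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform random partition into (train, test) index arrays.

    Train size is ceil(train_fraction * n); both parts must be non-empty.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = math.ceil(train_fraction * n)
    if n_train < 1 or n - n_train < 1:
        raise ValueError(f"degenerate split sizes ({n_train}, {n - n_train})")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split(
    ds: CropDataset, train_fraction: float, seed: int
) -> tuple[CropDataset, CropDataset]:
    """Split a dataset into disjoint, exhaustive train and test parts."""
    tr, te = split_indices(len(ds), train_fraction, seed)
    train, test = ds.copy(), ds.copy()
    train.frame = ds.frame.iloc[tr].reset_index(drop=True)
    test.frame = ds.frame.iloc[te].reset_index(drop=True)
    return train, test


@dataclass(frozen=True)
class PhaseSpec:
    train_fraction: float
    n_trials: int = 10

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction in (0, 1)")


DEFAULT_PHASES = (PhaseSpec(0.8, 10), PhaseSpec(0.5, 10), PhaseSpec(0.3, 10))

ModelSpec = RegressorSpec | BlendConfig


def _fit_predict(spec: ModelSpec, X_tr, y_tr, X_te) -> np.ndarray:
    if isinstance(spec, BlendConfig):
        return predict_krr(fit_krr(X_tr, y_tr, spec), X_te)
    return fit_model(spec, X_tr, y_tr).predict(X_te)


@dataclass
class MetricsReport:
    """Per-trial metric table plus averaged views.

    ``per_trial`` has one row per (model, phase, trial) with the four
    metric columns; ``by_phase()`` and ``pooled()`` average over trials
    and over everything respectively.
    """

    per_trial: pd.DataFrame

    def by_phase(self) -> pd.DataFrame:
        return (
            self.per_trial.groupby(["model", "train_fraction"], sort=False)[
                list(METRIC_NAMES)
            ]
            .mean()
            .reset_index()
        )

    def pooled(self) -> pd.DataFrame:
        return (
            self.per_trial.groupby("model", sort=False)[list(METRIC_NAMES)]
            .mean()
            .reset_index()
        )

    def table(self) -> pd.DataFrame:
        """Rows = models, columns = MAE/MSE/RMSE/R² (pooled means)."""
        t = self.pooled().set_index("model")
        t.columns = ["MAE", "MSE", "RMSE", "R2"]
        return t


def run_experiment(
    ds: CropDataset,
    model_specs: dict[str, ModelSpec],
    phases: tuple[PhaseSpec, ...] = DEFAULT_PHASES,
    seed: int = 42,
) -> MetricsReport:
    """Run the phase x trial protocol over a preprocessed dataset.

    Each trial draws a fresh seeded split, fits every model on the train
    part and scores the test part with all four metrics. Any model failure
    aborts with the model named.
    """
    if ds.frame[ds.frame.columns.intersection(["production"])].isna().any().any():
        raise ValueError("dataset has missing targets; preprocess first")
    X, y = ds.X, ds.y
    rows = []
    for phase in phases:
        for trial in range(phase.n_trials):
            tr, te = split_indices(len(y), phase.train_fraction, seed + trial)
            for name, spec in model_specs.items():
                try:
                    yhat = _fit_predict(spec, X[tr], y[tr], X[te])
                except Exception as exc:
                    raise RuntimeError(
                        f"model {name!r} failed in phase {phase.train_fraction} "
                        f"trial {trial}: {exc}"
                    ) from exc
                rows.append(
                    {
                        "model": name,
                        "train_fraction": phase.train_fraction,
                        "trial": trial,
                        **score_all(y[te], yhat),
                    }
                )
    return MetricsReport(per_trial=pd.DataFrame(rows))


def collect_test_errors(
    ds: CropDataset,
    model_specs: dict[str, ModelSpec],
    train_fraction: float = 0.8,
    seed: int = 42,
) -> pd.DataFrame:
    """One shared split; one column of aligned test-set errors per model.

    Errors are y - yhat on the test rows, the input the Diebold-Mariano
    comparison consumes.
    """
    X, y = ds.X, ds.y
    tr, te = split_indices(len(y), train_fraction, seed)
    out = {}
    for name, spec in model_specs.items():
        yhat = _fit_predict(spec, X[tr], y[tr], X[te])
        out[name] = y[te] - yhat
    return pd.DataFrame(out)
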