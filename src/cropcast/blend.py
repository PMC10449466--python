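"""KRR blending ensemble: KNN + random forest + ridge with a meta-combiner.

Blending is a second-order ensemble: the training rows are split once into a
base-train part and a blend-holdout part (10-15% of the training data, 15%
by default). The three base learners are fitted on base-train only, predict
the holdout, and a meta-learner maps those three prediction columns to the
holdout targets. The default meta-learner solves least squares over the
probability simplex (weights >= 0 summing to 1, no intercept), which makes
"the best combination of the predictors" literal and guarantees the blend's
holdout MSE never exceeds the best single base's. An unconstrained OLS meta
with intercept is available as ``meta="ols"``.

Unlike stacking, the bases are never refitted on the full training data:
the holdout slice exists precisely so the meta-learner sees predictions
from models that did not train on it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import FittedRegressor, RegressorSpec, fit as fit_base

__all__ = [
    "BlendConfig",
    "KRRModel",
    "fit_krr",
    "predict_krr",
    "solve_simplex_ls",
]


def _default_base_specs() -> tuple[RegressorSpec, RegressorSpec, RegressorSpec]:
    # base order (KNN, RF, ridge) is load-bearing: ties break toward lower index
    return (
        RegressorSpec("knn", {"k": 5}),
        RegressorSpec("rf", {"n_trees": 10}, seed=42),
        RegressorSpec("ridge", {"alpha": 0.01}),
    )


@dataclass(frozen=True)
class BlendConfig:
    holdout_fraction: float = 0.15
    base_specs: tuple[RegressorSpec, ...] = field(default_factory=_default_base_specs)
    meta: str = "simplex"
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.05 <= self.holdout_fraction <= 0.5:
            raise ValueError("holdout_fraction must lie in [0.05, 0.5]")
        if len(self.base_specs) != 3:
            raise ValueError("exactly three base specs required")
        if self.meta not in ("simplex", "ols"):
            raise ValueError(f"unknown meta-learner {self.meta!r}")


@dataclass
class KRRModel:
    base_models: tuple[FittedRegressor, FittedRegressor, FittedRegressor]
    meta_weights: np.ndarray
    intercept: float
    meta: str
    holdout_mse_by_base: np.ndarray
    holdout_mse_blend: float
    config: BlendConfig

    @property
    def n_features(self) -> int:
        return self.base_models[0].n_features


def solve_simplex_ls(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """argmin over {w >= 0, sum w = 1} of ||P w - y||^2, for 3 columns.

    Solved exactly by enumerating the seven possible supports (faces of the
    2-simplex), reducing each to an unconstrained least-squares problem via
    the sum-to-one substitution and keeping feasible candidates. Ties within
    a relative tolerance resolve to the earliest candidate in the order
    vertices (lowest index first), then edges, then the interior — so
    identical columns yield (1, 0, 0).
    """
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P must be n x 3")
    if P.shape[0] != y.shape[0]:
        raise ValueError("P and y row mismatch")
    if P.shape[0] < 3:
        raise ValueError("need at least 3 holdout rows")

    supports = (
        [(i,) for i in range(3)]
        + [(i, j) for i in range(3) for j in range(i + 1, 3)]
        + [(0, 1, 2)]
    )
    candidates: list[tuple[float, np.ndarray]] = []
    for sup in supports:
        w = np.zeros(3)
        if len(sup) == 1:
            w[sup[0]] = 1.0
        else:
            # substitute w_last = 1 - sum(others); solve the reduced lstsq
            base = sup[-1]
            free = sup[:-1]
            A = P[:, free] - P[:, [base]]
            b = y - P[:, base]
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
            w[list(free)] = coef
            w[base] = 1.0 - coef.sum()
            if np.any(w < -1e-10):
                continue
            w = np.clip(w, 0.0, None)
            w /= w.sum()
        obj = float(np.sum((P @ w - y) ** 2))
        candidates.append((obj, w))

    best = min(obj for obj, _ in candidates)
    tol = 1e-10 * max(1.0, best)
    for obj, w in candidates:  # first within-tolerance candidate wins the tie
        if obj <= best + tol:
            return w
    raise AssertionError("unreachable")


def fit_krr(X: np.ndarray, y: np.ndarray, config: BlendConfig | None = None) -> KRRModel:
    """Fit the blending ensemble.

    The rows are split uniformly at random (seeded) into base-train and a
    blend-holdout of ``ceil(holdout_fraction * n)`` rows; each base learner
    is fitted on base-train, predicts the holdout, and the meta-learner is
    fitted on those predictions. If the holdout targets are constant the
    meta-fit is degenerate: a warning is emitted and the weights default to
    the uniform (1/3, 1/3, 1/3).
    """
    config = config or BlendConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 20:
        raise ValueError(f"need >= 20 rows to blend, got {n}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values; impute first")
    n_holdout = math.ceil(config.holdout_fraction * n)
    if n_holdout < 3 or n - n_holdout < 3:
        raise ValueError("holdout_fraction leaves fewer than 3 rows in a split")

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    holdout_idx, train_idx = perm[:n_holdout], perm[n_holdout:]

    bases = tuple(fit_base(spec, X[train_idx], y[train_idx]) for spec in config.base_specs)
    P = np.column_stack([b.predict(X[holdout_idx]) for b in bases])
    y_hold = y[holdout_idx]

    intercept = 0.0
    if np.allclose(y_hold, y_hold[0]):
        warnings.warn(
            "blend holdout targets are constant; defaulting to uniform weights",
            stacklevel=2,
        )
        weights = np.full(3, 1.0 / 3.0)
    elif config.meta == "simplex":
        weights = solve_simplex_ls(P, y_hold)
    else:
        A = np.column_stack([P, np.ones(len(y_hold))])
        coef, *_ = np.linalg.lstsq(A, y_hold, rcond=None)
        weights, intercept = coef[:3], float(coef[3])

    mse_by_base = np.mean((P - y_hold[:, None]) ** 2, axis=0)
    blend_hold = P @ weights + intercept
    mse_blend = float(np.mean((blend_hold - y_hold) ** 2))
    if config.meta == "simplex" and not np.allclose(y_hold, y_hold[0]):
        # dominance is structural: every vertex of the simplex is feasible
        assert mse_blend <= mse_by_base.min() + 1e-9

    return KRRModel(
        base_models=bases,
        meta_weights=np.asarray(weights, dtype=float),
        intercept=intercept,
        meta=config.meta,
        holdout_mse_by_base=mse_by_base,
        holdout_mse_blend=mse_blend,
        config=config,
    )


def predict_krr(model: KRRModel, X: np.ndarray) -> np.ndarray:
    """Weighted combination of the base predictions (+ intercept for ols)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"expected (n, {model.n_features}) matrix, got {X.shape}")
    if X.shape[0] == 0:
        return np.empty(0)
    P = np.column_stack([b.predict(X) for b in model.base_models])
    return P @ model.meta_weights + model.intercept
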