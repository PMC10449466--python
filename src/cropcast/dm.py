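"""Diebold-Mariano comparison of two forecast-error series.

Given aligned error series e_A and e_B, the loss differential
d_t = L(e_A,t) - L(e_B,t) is averaged and scaled by its long-run variance
estimate sigma^2 = gamma_0 + 2 * sum_{k=1}^{h-1} gamma_k (1/T-normalized
autocovariances, so the estimate is positive semidefinite at h = 1):

    DM = mean(d) / sqrt(sigma^2 / T)

The test is oriented so that a large positive statistic (model A's loss
exceeding the reference model B's) gives a small one-sided p-value
p = 1 - Phi(DM), i.e. rejection means the reference model is significantly
more accurate. The small-sample variant applies the Harvey-Leybourne-Newbold
correction factor and a Student-t reference with T - 1 degrees of freedom.

Significance labels follow the star convention: "*" for p < 1%, "**" for
p < 5%, "***" for p < 10%, blank otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DMResult",
    "DegenerateSeriesError",
    "dm_statistic",
    "significance_label",
    "compare_all",
]


class DegenerateSeriesError(ValueError):
    """The loss differential has (numerically) zero variance."""


def significance_label(p_one_sided: float) -> str:
    """Map a one-sided p-value to the star convention."""
    if not 0.0 <= p_one_sided <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p_one_sided < 0.01:
        return "*"
    if p_one_sided < 0.05:
        return "**"
    if p_one_sided < 0.10:
        return "***"
    return ""


@dataclass
class DMResult:
    statistic: float
    p_one_sided: float
    p_two_sided: float
    n: int
    loss: str
    horizon: int
    label: str


def _autocovariance(d: np.ndarray, lag: int) -> float:
    # 1/T normalization (not 1/(T-k)) keeps sigma^2 >= 0 at h = 1
    T = d.size
    dc = d - d.mean()
    if lag == 0:
        return float(np.dot(dc, dc) / T)
    return float(np.dot(dc[lag:], dc[:-lag]) / T)


def dm_statistic(
    e_A: np.ndarray,
    e_B: np.ndarray,
    loss: str = "squared",
    horizon: int = 1,
    small_sample: bool = False,
) -> DMResult:
    """Compare error series A against reference series B.

    Rejection of H0 (small one-sided p) means model B is significantly more
    accurate than model A.
    """
    e_A = np.asarray(e_A, dtype=float)
    e_B = np.asarray(e_B, dtype=float)
    if e_A.shape != e_B.shape:
        raise ValueError("error series must have equal length")
    T = e_A.size
    if T < 4:
        raise ValueError("need at least 4 observations")
    if not (np.all(np.isfinite(e_A)) and np.all(np.isfinite(e_B))):
        raise ValueError("non-finite errors")
    if loss not in ("squared", "absolute"):
        raise ValueError(f"unknown loss {loss!r}")
    if horizon < 1:
        raise ValueError("horizon >= 1")

    L = np.square if loss == "squared" else np.abs
    d = L(e_A) - L(e_B)
    dbar = float(d.mean())

    gamma0 = _autocovariance(d, 0)
    if gamma0 < 1e-12 * max(1.0, dbar * dbar):
        raise DegenerateSeriesError(
            "loss differential has ~zero variance "
            "(identical losses or a constant differential)"
        )
    sigma2 = gamma0 + 2.0 * sum(_autocovariance(d, k) for k in range(1, horizon))
    sigma2 = max(sigma2, gamma0 * 1e-12)

    stat = dbar / math.sqrt(sigma2 / T)
    if small_sample:
        h = horizon
        correction = math.sqrt((T + 1 - 2 * h + h * (h - 1) / T) / T)
        stat *= correction
        p_one = float(stats.t.sf(stat, df=T - 1))
    else:
        p_one = float(stats.norm.sf(stat))
    p_two = 2.0 * min(p_one, 1.0 - p_one)
    return DMResult(
        statistic=float(stat),
        p_one_sided=p_one,
        p_two_sided=p_two,
        n=T,
        loss=loss,
        horizon=horizon,
        label=significance_label(p_one),
    )


def compare_all(
    errors: pd.DataFrame,
    reference: str,
    loss: str = "squared",
    horizon: int = 1,
    small_sample: bool = False,
) -> pd.DataFrame:
    """DM comparison of every model column against the reference column.

    ``errors`` holds one column of aligned test-set errors per model. The
    result has one row per non-reference model with the statistic, both
    p-values, and the significance label (the reference has no self-row).
    """
    if reference not in errors.columns:
        raise KeyError(f"reference model {reference!r} not in errors table")
    rows = []
    ref = errors[reference].to_numpy()
    for name in errors.columns:
        if name == reference:
            continue
        res = dm_statistic(
            errors[name].to_numpy(), ref, loss=loss, horizon=horizon,
            small_sample=small_sample,
        )
        rows.append(
            {
                "model": name,
                "dm": res.statistic,
                "p_one_sided": res.p_one_sided,
                "p_two_sided": res.p_two_sided,
                "label": res.label,
            }
        )
    return pd.DataFrame(rows)
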