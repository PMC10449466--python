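"""Threshold-based crop recommendation.

For a land unit described by its environmental and area features, each
candidate crop's production is predicted by its trained model and compared
with an expert-supplied minimum threshold tau (tons) for the region and
season. Crops meeting the threshold qualify; they are ranked by relative
margin (P - tau) / tau — relative rather than absolute so high-volume crops
(rice, tons) do not trivially dominate low-volume ones (wheat) — and the
top-ranked crop is the recommendation. Candidates are restricted to crops
whose harvest season matches the query season.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .blend import KRRModel, predict_krr
from .models import FittedRegressor
from .schema import CROPS, Season

__all__ = [
    "ThresholdTable",
    "Recommendation",
    "ConfigurationError",
    "recommend",
    "recommend_report",
    "recommendation_from_json",
]

_EPS = 1e-9  # tau = 0 guard in the margin denominator


class ConfigurationError(KeyError):
    """A candidate crop lacks a model, features, or a threshold entry."""


@dataclass
class ThresholdTable:
    """Expert minimum-production thresholds per (region, season, crop)."""

    entries: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def add(self, region: str, season: str, crop: str, tau: float) -> None:
        if tau < 0:
            raise ValueError("tau must be >= 0")
        key = (region, str(Season(season).value), crop)
        if key in self.entries:
            raise ValueError(f"duplicate threshold entry {key}")
        self.entries[key] = float(tau)

    def lookup(self, region: str, season: str, crop: str) -> float:
        key = (region, str(Season(season).value), crop)
        if key not in self.entries:
            raise ConfigurationError(f"no threshold for {key}")
        return self.entries[key]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdTable":
        df = pd.read_csv(path)
        required = {"region", "season", "crop", "tau_tons"}
        if not required.issubset(df.columns):
            raise ValueError(f"threshold CSV must have columns {sorted(required)}")
        table = cls()
        for _, row in df.iterrows():
            table.add(str(row["region"]), str(row["season"]), str(row["crop"]),
                      float(row["tau_tons"]))
        return table


@dataclass
class Recommendation:
    """Qualifying crops sorted by descending relative margin, plus top pick."""

    qualifying: list[dict[str, Any]]
    top_pick: str | None
    region: str
    season: str
    all_predictions: dict[str, float] = field(default_factory=dict)


def _predict_one(model: Any, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).reshape(1, -1)
    if isinstance(model, KRRModel):
        return float(predict_krr(model, x)[0])
    if isinstance(model, FittedRegressor):
        return float(model.predict(x)[0])
    return float(np.asarray(model.predict(x), dtype=float)[0])


def recommend(
    models: dict[str, Any],
    features: dict[str, np.ndarray],
    thresholds: ThresholdTable,
    region: str,
    season: str,
) -> Recommendation:
    """Predict each season-matching crop's production and filter by threshold.

    ``models`` maps crop name to a fitted regressor or KRR ensemble;
    ``features`` maps crop name to that crop's feature vector on the model's
    training scale. A crop qualifies when its predicted production meets its
    threshold; ties in margin break alphabetically by crop name.
    """
    season = str(Season(season).value)
    candidates = sorted(c for c in features if CROPS[c].season.value == season)
    rows = []
    predictions: dict[str, float] = {}
    for crop in candidates:
        if crop not in models:
            raise ConfigurationError(f"no model for crop {crop!r}")
        tau = thresholds.lookup(region, season, crop)
        pred = _predict_one(models[crop], features[crop])
        predictions[crop] = pred
        if pred >= tau:
            margin = (pred - tau) / max(tau, _EPS)
            rows.append(
                {"crop": crop, "predicted_production": pred, "tau": tau,
                 "margin": margin}
            )
    rows.sort(key=lambda r: (-r["margin"], r["crop"]))
    return Recommendation(
        qualifying=rows,
        top_pick=rows[0]["crop"] if rows else None,
        region=region,
        season=season,
        all_predictions=predictions,
    )


def recommend_report(rec: Recommendation) -> tuple[str, str]:
    """Render a recommendation as (human-readable text, JSON string)."""
    lines = [f"Recommendation for region {rec.region!r}, season {rec.season}:"]
    if not rec.qualifying:
        lines.append("  no crop qualifies (every prediction is below its threshold)")
    else:
        lines.append(f"  top pick: {rec.top_pick}")
        lines.append(f"  {'crop':<8} {'predicted (t)':>14} {'tau (t)':>10} {'margin':>8}")
        for row in rec.qualifying:
            lines.append(
                f"  {row['crop']:<8} {row['predicted_production']:>14.3f} "
                f"{row['tau']:>10.3f} {row['margin']:>8.3f}"
            )
    payload = {
        "region": rec.region,
        "season": rec.season,
        "top_pick": rec.top_pick,
        "qualifying": rec.qualifying,
        "all_predictions": rec.all_predictions,
    }
    return "\n".join(lines), json.dumps(payload, indent=1)


def recommendation_from_json(text: str) -> Recommendation:
    """Re-parse a JSON report back into an equal Recommendation."""
    d = json.loads(text)
    return Recommendation(
        qualifying=d["qualifying"],
        top_pick=d["top_pick"],
        region=d["region"],
        season=d["season"],
        all_predictions=d.get("all_predictions", {}),
    )
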