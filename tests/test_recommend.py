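"""Threshold recommender: filter, ranking, oracle equivalence."""

import numpy as np
import pytest

from cropcast.recommend import (
    ConfigurationError,
    Recommendation,
    ThresholdTable,
    recommend,
    recommend_report,
    recommendation_from_json,
)
from cropcast.schema import CROPS


class FixedModel:
    """Predicts a constant regardless of features."""

    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


def setup_case(predictions, thresholds, season="kharif", region="r"):
    models = {c: FixedModel(v) for c, v in predictions.items()}
    features = {c: np.zeros(8) for c in predictions}
    table = ThresholdTable()
    for c, tau in thresholds.items():
        table.add(region, season, c, tau)
    return models, features, table


def brute_force(predictions, thresholds, season):
    """Oracle: plain filter-and-sort over (prediction, threshold) pairs."""
    rows = []
    for crop, pred in predictions.items():
        if CROPS[crop].season.value != season:
            continue
        tau = thresholds[crop]
        if pred >= tau:
            rows.append((crop, pred, tau, (pred - tau) / max(tau, 1e-9)))
    rows.sort(key=lambda r: (-r[3], r[0]))
    return rows


class TestRecommend:
    def test_basic_filter(self):
        models, feats, table = setup_case(
            {"aus": 5.0, "boro": 1.0}, {"aus": 4.0, "boro": 2.0}
        )
        rec = recommend(models, feats, table, "r", "kharif")
        assert [q["crop"] for q in rec.qualifying] == ["aus"]
        assert rec.top_pick == "aus"

    def test_nothing_qualifies(self):
        models, feats, table = setup_case({"aus": 1.0}, {"aus": 100.0})
        rec = recommend(models, feats, table, "r", "kharif")
        assert rec.qualifying == [] and rec.top_pick is None

    def test_relative_margin_ordering(self):
        models, feats, table = setup_case(
            {"aus": 10.0, "boro": 10.0}, {"aus": 5.0, "boro": 8.0}
        )
        rec = recommend(models, feats, table, "r", "kharif")
        assert [q["crop"] for q in rec.qualifying] == ["aus", "boro"]
        assert rec.qualifying[0]["margin"] == pytest.approx(1.0)
        assert rec.qualifying[1]["margin"] == pytest.approx(0.25)

    def test_margin_tie_breaks_alphabetically(self):
        models, feats, table = setup_case(
            {"boro": 10.0, "aus": 10.0}, {"boro": 5.0, "aus": 5.0}
        )
        rec = recommend(models, feats, table, "r", "kharif")
        assert [q["crop"] for q in rec.qualifying] == ["aus", "boro"]

    def test_season_filters_candidates(self):
        models, feats, table = setup_case(
            {"aman": 10.0, "wheat": 10.0}, {"aman": 1.0, "wheat": 1.0},
            season="rabi",
        )
        # kharif crops present in features but not thresholded for rabi
        feats["aus"] = np.zeros(8)
        models["aus"] = FixedModel(100.0)
        rec = recommend(models, feats, table, "r", "rabi")
        assert set(q["crop"] for q in rec.qualifying) == {"aman", "wheat"}

    def test_zero_threshold_guard(self):
        models, feats, table = setup_case({"aus": 2.0}, {"aus": 0.0})
        rec = recommend(models, feats, table, "r", "kharif")
        assert np.isfinite(rec.qualifying[0]["margin"])

    def test_missing_threshold_raises(self):
        models, feats, _ = setup_case({"aus": 2.0}, {"aus": 1.0})
        with pytest.raises(ConfigurationError, match="aus"):
            recommend(models, feats, ThresholdTable(), "r", "kharif")

    def test_missing_model_raises(self):
        models, feats, table = setup_case({"aus": 2.0}, {"aus": 1.0})
        del models["aus"]
        with pytest.raises(ConfigurationError, match="aus"):
            recommend(models, feats, table, "r", "kharif")

    def test_deterministic(self):
        models, feats, table = setup_case(
            {"aus": 5.0, "boro": 3.0, "potato": 4.0},
            {"aus": 1.0, "boro": 1.0, "potato": 1.0},
        )
        r1 = recommend(models, feats, table, "r", "kharif")
        r2 = recommend(models, feats, table, "r", "kharif")
        assert r1.qualifying == r2.qualifying and r1.top_pick == r2.top_pick


def test_oracle_equivalence_random_instances():
    """recommend() matches brute-force filter-and-sort on 1,000 instances."""
    g = np.random.default_rng(7)
    kharif = [c for c in CROPS if CROPS[c].season.value == "kharif"]
    for _ in range(1000):
        preds = {c: float(np.round(g.uniform(0, 10), 2)) for c in kharif}
        taus = {c: float(np.round(g.uniform(0, 10), 2)) for c in kharif}
        models, feats, table = setup_case(preds, taus)
        rec = recommend(models, feats, table, "r", "kharif")
        expected = brute_force(preds, taus, "kharif")
        got = [
            (q["crop"], q["predicted_production"], q["tau"], q["margin"])
            for q in rec.qualifying
        ]
        assert got == pytest.approx(expected) if got else got == expected
        assert rec.top_pick == (expected[0][0] if expected else None)


def test_raising_threshold_is_monotone():
    g = np.random.default_rng(13)
    kharif = [c for c in CROPS if CROPS[c].season.value == "kharif"]
    for _ in range(200):
        preds = {c: float(g.uniform(0, 10)) for c in kharif}
        taus = {c: float(g.uniform(0, 10)) for c in kharif}
        target = kharif[int(g.integers(len(kharif)))]
        models, feats, table = setup_case(preds, taus)
        before = recommend(models, feats, table, "r", "kharif")
        taus_up = dict(taus, **{target: taus[target] + float(g.uniform(0, 5))})
        models, feats, table = setup_case(preds, taus_up)
        after = recommend(models, feats, table, "r", "kharif")
        rank_b = [q["crop"] for q in before.qualifying]
        rank_a = [q["crop"] for q in after.qualifying]
        if target not in rank_b:
            assert target not in rank_a  # excluded stays excluded
        elif target in rank_a:
            assert rank_a.index(target) >= rank_b.index(target)


class TestReport:
    def test_empty_recommendation_explicit(self):
        rec = Recommendation([], None, "r", "kharif")
        text, payload = recommend_report(rec)
        assert "no crop qualifies" in text
        assert recommendation_from_json(payload).top_pick is None

    def test_one_row_table(self):
        models, feats, table = setup_case({"aus": 5.0}, {"aus": 4.0})
        rec = recommend(models, feats, table, "r", "kharif")
        text, _ = recommend_report(rec)
        assert text.count("aus") >= 2  # top pick line + table row

    def test_json_roundtrip(self):
        models, feats, table = setup_case(
            {"aus": 5.0, "boro": 3.0}, {"aus": 4.0, "boro": 1.0}
        )
        rec = recommend(models, feats, table, "r", "kharif")
        _, payload = recommend_report(rec)
        back = recommendation_from_json(payload)
        assert back == rec


def test_threshold_table_duplicate_entry_rejected():
    table = ThresholdTable()
    table.add("r", "kharif", "aus", 1.0)
    with pytest.raises(ValueError, match="duplicate"):
        table.add("r", "kharif", "aus", 2.0)
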