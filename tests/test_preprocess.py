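"""Cleaning, integration, reduction, and min-max normalization."""

import numpy as np
import pandas as pd
import pytest

import cropcast as cc
from cropcast import preprocess as pp
from cropcast.schema import NUMERIC_COLUMNS, WEATHER_COLUMNS

from test_schema import _row, make_ds


class TestImpute:
    def test_mean_of_observed(self):
        ds = make_ds([_row(rainfall=4.0), _row(year=2001, rainfall=np.nan),
                      _row(year=2002, rainfall=8.0)])
        out, rep = pp.impute_missing(ds)
        assert out.frame["rainfall"].tolist() == [4.0, 6.0, 8.0]
        assert rep.n_imputed_by_column["rainfall"] == 1

    def test_no_missing_is_identity(self, small_ds):
        out, rep = pp.impute_missing(small_ds)
        assert rep.n_imputed == 0
        pd.testing.assert_frame_equal(out.frame, small_ds.frame)

    def test_all_missing_column_raises(self):
        ds = make_ds([_row(rainfall=np.nan), _row(year=2001, rainfall=np.nan)])
        with pytest.raises(pp.ImputationError, match="rainfall"):
            pp.impute_missing(ds)

    def test_idempotent_and_mean_preserving(self, small_ds):
        ds = cc.inject_missing(small_ds, 0.2, seed=9)
        means_before = {c: ds.frame[c].mean() for c in NUMERIC_COLUMNS}
        once, _ = pp.impute_missing(ds)
        twice, rep2 = pp.impute_missing(once)
        assert rep2.n_imputed == 0
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        for c in NUMERIC_COLUMNS:
            assert once.frame[c].mean() == pytest.approx(means_before[c], rel=1e-12)

    def test_neighbor_strategy_interpolates_within_series(self):
        rows = [_row(year=y, rainfall=r) for y, r in
                [(2000, 10.0), (2001, np.nan), (2002, 30.0)]]
        out, _ = pp.impute_missing(make_ds(rows), strategy="neighbor")
        assert out.frame["rainfall"].tolist() == [10.0, 20.0, 30.0]

    def test_neighbor_falls_back_to_column_mean_at_edges(self):
        rows = [_row(year=y, rainfall=r) for y, r in
                [(2000, np.nan), (2001, 10.0), (2002, 30.0)]]
        out, _ = pp.impute_missing(make_ds(rows), strategy="neighbor")
        assert out.frame["rainfall"].iloc[0] == pytest.approx(20.0)


class TestCoerce:
    def test_thousands_separator_stripped(self):
        ds = make_ds([_row()])
        ds.frame["rainfall"] = ["1,250"]
        out, _ = pp.coerce_and_filter(ds)
        assert out.frame["rainfall"].iloc[0] == 1250.0

    def test_out_of_bounds_becomes_missing(self):
        ds = make_ds([_row(humidity=150.0)])
        out, rep = pp.coerce_and_filter(ds)
        assert np.isnan(out.frame["humidity"].iloc[0])
        assert rep.n_coerced == 1

    def test_crossed_temperatures_both_blanked(self):
        ds = make_ds([_row(temp_min=25.0, temp_max=20.0)])
        out, rep = pp.coerce_and_filter(ds)
        assert np.isnan(out.frame["temp_min"].iloc[0])
        assert np.isnan(out.frame["temp_max"].iloc[0])
        assert rep.n_coerced == 2


def _wx(rows):
    cols = ["district", "year", "month"] + WEATHER_COLUMNS
    return pd.DataFrame(rows, columns=cols)


def _wx_row(district, year, month, rainfall):
    return [district, year, month, rainfall, 30.0, 20.0, 75.0, 5.0, 3.0, 6.0]


class TestAggregateWeather:
    def test_aus_mean_over_window(self):
        wx = _wx([_wx_row("d1", 2000, m, r) for m, r in [(6, 100), (7, 200), (8, 300)]])
        out = pp.aggregate_weather(wx, "aus", "d1", 2000)
        assert out["rainfall"] == pytest.approx(200.0)

    def test_aman_wraps_year_boundary(self):
        wx = _wx([_wx_row("d1", 1999, 12, 10.0), _wx_row("d1", 2000, 1, 30.0)])
        out = pp.aggregate_weather(wx, "aman", "d1", 2000)
        assert out["rainfall"] == pytest.approx(20.0)

    def test_missing_month_raises_with_key(self):
        wx = _wx([_wx_row("d1", 2000, 6, 100.0)])
        with pytest.raises(pp.AggregationError, match=r"\(2000, 7\)"):
            pp.aggregate_weather(wx, "aus", "d1", 2000)


class TestIntegrate:
    @staticmethod
    def _tables():
        wx = _wx(
            [_wx_row(d, 2000, m, r)
             for d in ("d1", "d2")
             for m, r in [(6, 100), (7, 200), (8, 300)]]
        )
        wx.loc[wx["district"] == "d2", "rainfall"] += 60
        areas = pd.DataFrame(
            [["d1", 2000, "aus", 1000.0], ["d2", 2000, "aus", 2000.0]],
            columns=["district", "year", "crop", "area"],
        )
        prods = pd.DataFrame(
            [["d1", 2000, "aus", 500.0], ["d2", 2000, "aus", 900.0]],
            columns=["district", "year", "crop", "production"],
        )
        return wx, areas, prods

    def test_two_district_join(self):
        wx, areas, prods = self._tables()
        ds = pp.integrate(wx, areas, prods)
        assert len(ds) == 2
        by_d = ds.frame.set_index("district")
        assert by_d.at["d1", "rainfall"] == pytest.approx(200.0)
        assert by_d.at["d2", "rainfall"] == pytest.approx(260.0)

    def test_area_without_production_excluded(self):
        wx, areas, prods = self._tables()
        ds = pp.integrate(wx, areas, prods.iloc[:1])
        assert ds.frame["district"].tolist() == ["d1"]

    def test_empty_join_warns_not_raises(self):
        wx, areas, prods = self._tables()
        with pytest.warns(UserWarning, match="empty"):
            ds = pp.integrate(wx, areas.iloc[0:0], prods)
        assert len(ds) == 0


class TestReduce:
    def test_duplicates_dropped_first_kept(self):
        ds = make_ds([_row(), _row()])
        out, rep = pp.reduce(ds)
        assert len(out) == 1
        assert rep.n_dropped_duplicates == 1

    def test_all_predictors_missing_is_junk(self):
        junk = _row(**{c: np.nan for c in cc.PREDICTOR_COLUMNS})
        out, rep = pp.reduce(make_ds([_row(), junk]))
        assert len(out) == 1
        assert rep.n_dropped_junk == 1

    def test_clean_dataset_unchanged(self, small_ds):
        out, rep = pp.reduce(small_ds)
        assert rep.n_dropped_duplicates == rep.n_dropped_junk == 0
        pd.testing.assert_frame_equal(out.frame, small_ds.frame)

    def test_never_increases_rows_and_keys_unique(self, small_ds):
        ds = cc.inject_duplicates(small_ds, 0.3, seed=4)
        out, _ = pp.reduce(ds)
        assert len(out) <= len(ds)
        assert not out.frame.duplicated(subset=["district", "year", "crop"]).any()


class TestMinMax:
    def test_fit_min_max(self):
        ds = make_ds([_row(rainfall=2.0), _row(year=2001, rainfall=4.0),
                      _row(year=2002, rainfall=6.0)])
        params = pp.minmax_fit(ds, columns=["rainfall"])
        assert params.bounds["rainfall"] == (2.0, 6.0)

    def test_apply_closed_form(self):
        ds = make_ds([_row(rainfall=2.0), _row(year=2001, rainfall=4.0),
                      _row(year=2002, rainfall=6.0)])
        params = pp.minmax_fit(ds, columns=["rainfall"])
        out = pp.minmax_apply(ds, params)
        assert out.frame["rainfall"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_column_maps_to_zero(self):
        ds = make_ds([_row(), _row(year=2001)])
        params = pp.minmax_fit(ds, columns=["rainfall"])
        out = pp.minmax_apply(ds, params)
        assert (out.frame["rainfall"] == 0.0).all()

    def test_invert_is_inverse(self, small_ds):
        params = pp.minmax_fit(small_ds)
        back = pp.minmax_invert(pp.minmax_apply(small_ds, params), params)
        for c in NUMERIC_COLUMNS:
            np.testing.assert_allclose(
                back.frame[c].astype(float), small_ds.frame[c].astype(float),
                rtol=1e-12, atol=1e-12,
            )

    def test_fitting_data_lands_in_unit_interval(self, normalized_ds):
        for c in NUMERIC_COLUMNS:
            v = normalized_ds.frame[c].astype(float)
            assert v.min() >= -1e-12 and v.max() <= 1 + 1e-12

    def test_test_values_outside_unit_not_clipped(self):
        train = make_ds([_row(rainfall=2.0), _row(year=2001, rainfall=6.0)])
        params = pp.minmax_fit(train, columns=["rainfall"])
        test = make_ds([_row(rainfall=10.0)])
        out = pp.minmax_apply(test, params)
        assert out.frame["rainfall"].iloc[0] == pytest.approx(2.0)


def test_full_chain_deterministic(small_ds):
    ds = cc.inject_missing(small_ds, 0.1, seed=21)
    runs = []
    for _ in range(2):
        out, _, _ = pp.clean_pipeline(ds.copy())
        runs.append(out.frame)
    pd.testing.assert_frame_equal(runs[0], runs[1])
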