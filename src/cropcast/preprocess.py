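"""Preprocessing pipeline: cleaning, integration, reduction, normalization.

Four stages prepare raw records for model training:

1. **Cleaning** — format coercion (whitespace / thousands separators),
   plausibility bounds, the temp_min <= temp_max cross-field rule, and mean
   imputation of missing cells (optionally neighbor interpolation within a
   (district, crop) series ordered by year).
2. **Integration** — joining monthly weather, cultivation area and production
   tables into one record per (district, year, crop), averaging each weather
   variable over the crop's responsible months.
3. **Reduction** — dropping exact duplicates and junk rows (every predictor
   missing).
4. **Normalization** — classical min-max scaling with parameters fitted on
   training data only (a ``global_fit`` escape hatch fits on the full table
   instead, reproducing pipelines that normalize before splitting).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    ALL_COLUMNS,
    CROPS,
    KEY_COLUMNS,
    NUMERIC_COLUMNS,
    PREDICTOR_COLUMNS,
    WEATHER_COLUMNS,
    CropDataset,
    CropKind,
    NormalizationParams,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningReport",
    "ImputationError",
    "AggregationError",
    "DEFAULT_BOUNDS",
    "impute_missing",
    "coerce_and_filter",
    "aggregate_weather",
    "integrate",
    "reduce",
    "minmax_fit",
    "minmax_apply",
    "minmax_invert",
    "clean_pipeline",
]


class ImputationError(ValueError):
    """A column has no observed values to impute from."""


class AggregationError(ValueError):
    """A weather window is incomplete for the requested key."""


@dataclass
class CleaningReport:
    n_imputed_by_column: dict[str, int] = field(default_factory=dict)
    n_coerced: int = 0
    n_dropped_duplicates: int = 0
    n_dropped_junk: int = 0

    @property
    def n_imputed(self) -> int:
        return sum(self.n_imputed_by_column.values())

    def merged(self, other: "CleaningReport") -> "CleaningReport":
        imputed = dict(self.n_imputed_by_column)
        for c, n in other.n_imputed_by_column.items():
            imputed[c] = imputed.get(c, 0) + n
        return CleaningReport(
            n_imputed_by_column=imputed,
            n_coerced=self.n_coerced + other.n_coerced,
            n_dropped_duplicates=self.n_dropped_duplicates + other.n_dropped_duplicates,
            n_dropped_junk=self.n_dropped_junk + other.n_dropped_junk,
        )


#: Generous physical plausibility bounds used by default at coercion time.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "rainfall": (0.0, 5000.0),
    "temp_max": (-10.0, 60.0),
    "temp_min": (-20.0, 50.0),
    "humidity": (0.0, 100.0),
    "wind_speed": (0.0, 500.0),
    "cloud_coverage": (0.0, 100.0),
    "sunshine": (0.0, 24.0),
    "area": (0.0, 1e9),
    "production": (0.0, 1e9),
}


def impute_missing(
    ds: CropDataset, strategy: str = "mean"
) -> tuple[CropDataset, CleaningReport]:
    """Fill missing numeric cells.

    ``strategy="mean"`` replaces each missing cell with the arithmetic mean
    of the column's observed values. ``strategy="neighbor"`` interpolates
    between the previous and next observed values within each
    (district, crop) series ordered by year, falling back to the column mean
    at series edges. Both are idempotent; non-missing cells are untouched.
    """
    if strategy not in ("mean", "neighbor"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = ds.copy()
    f = out.frame
    report = CleaningReport()
    for col in NUMERIC_COLUMNS:
        missing = f[col].isna()
        n_miss = int(missing.sum())
        if n_miss == 0:
            report.n_imputed_by_column[col] = 0
            continue
        observed = f[col].dropna()
        if observed.empty:
            raise ImputationError(f"column {col!r} has no observed values")
        if strategy == "neighbor":
            filled = f[col].copy()
            order = f.sort_values(["district", "crop", "year"]).index
            by_series = (
                f.loc[order, col]
                .groupby([f.loc[order, "district"], f.loc[order, "crop"]], sort=False)
                .transform(lambda s: s.interpolate(limit_area="inside"))
            )
            filled.loc[order] = by_series
            filled = filled.fillna(observed.mean())
            f[col] = filled
        else:
            f[col] = f[col].fillna(observed.mean())
        report.n_imputed_by_column[col] = n_miss
    return out, report


def coerce_and_filter(
    ds: CropDataset, bounds: dict[str, tuple[float, float]] | None = None
) -> tuple[CropDataset, CleaningReport]:
    """Coerce formats and blank implausible values.

    Values outside the per-column plausibility bounds become missing and are
    counted; rows where temp_min > temp_max have both temperatures blanked.
    (Numeric parsing with separator stripping happens at read time; this
    stage re-applies it for frames built in memory from strings.)
    """
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    out = ds.copy()
    f = out.frame
    report = CleaningReport()
    for col in NUMERIC_COLUMNS:
        if f[col].dtype == object:  # in-memory strings: strip "1,250" etc.
            cleaned = (
                f[col]
                .astype(str)
                .str.replace(",", "", regex=False)
                .str.strip()
                .replace({"": None, "nan": None, "None": None})
            )
            f[col] = pd.to_numeric(cleaned, errors="coerce")
        else:
            f[col] = f[col].astype(float)
        lo, hi = bounds[col]
        bad = f[col].notna() & ((f[col] < lo) | (f[col] > hi))
        report.n_coerced += int(bad.sum())
        f.loc[bad, col] = np.nan
    crossed = f["temp_min"].notna() & f["temp_max"].notna() & (f["temp_min"] > f["temp_max"])
    report.n_coerced += 2 * int(crossed.sum())
    f.loc[crossed, ["temp_min", "temp_max"]] = np.nan
    return out, report


def _window_rows(
    wx: pd.DataFrame, crop: CropKind, district: str, year: int
) -> pd.DataFrame:
    months = crop.window_months(year)
    sel = wx[(wx["district"] == district)]
    picked, missing = [], []
    for yy, mm in months:
        row = sel[(sel["year"] == yy) & (sel["month"] == mm)]
        if row.empty:
            missing.append((yy, mm))
        else:
            picked.append(row.iloc[0])
    if missing:
        raise AggregationError(
            f"missing weather month(s) for ({district!r}, {year}, {crop.name}): {missing}"
        )
    return pd.DataFrame(picked)


def aggregate_weather(
    wx: pd.DataFrame, crop: CropKind | str, district: str, year: int
) -> dict[str, float]:
    """Average the 7 weather variables over the crop's window months.

    ``wx`` is a monthly weather table with columns (district, year, month)
    plus the seven weather variables, at most one row per key. Wrapping
    windows draw their early months from ``year - 1``.
    """
    if isinstance(crop, str):
        crop = CROPS[crop]
    rows = _window_rows(wx, crop, district, year)
    return {col: float(rows[col].mean()) for col in WEATHER_COLUMNS}


def integrate(
    wx: pd.DataFrame, areas: pd.DataFrame, productions: pd.DataFrame
) -> CropDataset:
    """Inner-join weather, area and production tables into one dataset.

    ``areas`` has columns (district, year, crop, area); ``productions`` has
    (district, year, crop, production). Keys whose weather window is
    incomplete are excluded, consistent with inner-join semantics. An empty
    result warns rather than raises.
    """
    merged = areas.merge(productions, on=KEY_COLUMNS, how="inner")
    records = []
    for _, row in merged.iterrows():
        crop = CROPS[str(row["crop"]).lower()]
        try:
            weather = aggregate_weather(wx, crop, row["district"], int(row["year"]))
        except AggregationError:
            continue
        rec = {
            "district": row["district"],
            "year": int(row["year"]),
            "crop": crop.name,
            **weather,
            "area": float(row["area"]),
            "production": float(row["production"]),
        }
        records.append(rec)
    if not records:
        warnings.warn("integration produced an empty dataset", stacklevel=2)
        return CropDataset.empty()
    frame = pd.DataFrame.from_records(records, columns=ALL_COLUMNS)
    return CropDataset(frame)


def reduce(ds: CropDataset) -> tuple[CropDataset, CleaningReport]:
    """Drop exact duplicate rows (keeping the first) and junk rows.

    Junk = rows whose every predictor cell is missing. Row order is
    otherwise stable.
    """
    out = ds.copy()
    f = out.frame
    report = CleaningReport()
    dup = f.duplicated(keep="first")
    report.n_dropped_duplicates = int(dup.sum())
    f = f[~dup]
    junk = f[PREDICTOR_COLUMNS].isna().all(axis=1)
    report.n_dropped_junk = int(junk.sum())
    f = f[~junk]
    out.frame = f.reset_index(drop=True)
    return out, report


def minmax_fit(ds: CropDataset, columns: list[str] | None = None) -> NormalizationParams:
    """Fit per-column min/max on the given dataset (run after imputation)."""
    columns = columns or NUMERIC_COLUMNS
    f = ds.frame
    bounds = {}
    for col in columns:
        v = f[col].astype(float)
        if v.isna().any():
            raise ValueError(f"column {col!r} has missing values; impute first")
        bounds[col] = (float(v.min()), float(v.max()))
    return NormalizationParams(bounds)


def minmax_apply(ds: CropDataset, params: NormalizationParams) -> CropDataset:
    """Scale each covered column to x' = (x - min) / (max - min).

    Constant columns (max == min) map to 0.0 with a logged warning.
    Out-of-range values (e.g. test data beyond the training extremes) are
    NOT clipped.
    """
    out = ds.copy()
    f = out.frame
    for col, (lo, hi) in params.bounds.items():
        if hi == lo:
            logger.warning("column %r is constant (min == max); mapping to 0.0", col)
            f[col] = 0.0
        else:
            f[col] = (f[col].astype(float) - lo) / (hi - lo)
    out.normalization_state = "normalized"
    out.norm_params = params
    return out


def minmax_invert(ds: CropDataset, params: NormalizationParams) -> CropDataset:
    """Invert min-max scaling: x = x' * (max - min) + min."""
    out = ds.copy()
    f = out.frame
    for col, (lo, hi) in params.bounds.items():
        f[col] = f[col].astype(float) * (hi - lo) + lo
    out.normalization_state = "raw"
    out.norm_params = None
    return out


def clean_pipeline(
    ds: CropDataset,
    bounds: dict[str, tuple[float, float]] | None = None,
    impute: str = "mean",
    normalize: bool = True,
    global_fit: bool = True,
) -> tuple[CropDataset, CleaningReport, NormalizationParams | None]:
    """Run coerce -> impute -> reduce (-> normalize) on one table.

    With ``normalize=True`` and ``global_fit=True`` the min-max parameters
    are fitted on the whole cleaned table (the convenient single-table
    path); leakage-free pipelines pass ``normalize=False`` and fit
    parameters on their training split via :func:`minmax_fit`.
    """
    ds1, rep1 = coerce_and_filter(ds, bounds)
    ds2, rep2 = reduce(ds1)
    ds3, rep3 = impute_missing(ds2, strategy=impute)
    report = rep1.merged(rep2).merged(rep3)
    params = None
    if normalize and global_fit:
        params = minmax_fit(ds3)
        ds3 = minmax_apply(ds3, params)
    return ds3, report, params
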