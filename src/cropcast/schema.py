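"""Dataset schema: crops, seasonal weather windows, CSV I/O and validation.

The unit of observation is one (district, harvest fiscal year, crop) record
carrying seven seasonal weather averages, the cultivated area in acres, and
the production in tons. Five crops are modelled — the three Bangladeshi rice
seasons (aus, aman, boro) plus potato and wheat — each with its own window of
months whose weather drives the harvest. Windows that straddle the calendar
year boundary (aman, wheat) are attributed to the harvest fiscal year of the
later month.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "CropKind",
    "CROPS",
    "KEY_COLUMNS",
    "PREDICTOR_COLUMNS",
    "TARGET_COLUMN",
    "ALL_COLUMNS",
    "NormalizationParams",
    "CropDataset",
    "ValidationReport",
    "SchemaError",
    "read_dataset",
    "write_dataset",
    "validate",
]


class Season(str, enum.Enum):
    KHARIF = "kharif"
    RABI = "rabi"


@dataclass(frozen=True)
class CropKind:
    """A crop with its harvest season and weather-window month range.

    ``window`` is an inclusive (first_month, last_month) pair; when
    first_month > last_month the window wraps the year boundary and the
    early months belong to the calendar year before the harvest year.
    """

    name: str
    season: Season
    window: tuple[int, int]

    @property
    def wraps(self) -> bool:
        return self.window[0] > self.window[1]

    def window_months(self, harvest_year: int) -> list[tuple[int, int]]:
        """Resolve the window to concrete (year, month) pairs."""
        first, last = self.window
        if not self.wraps:
            return [(harvest_year, m) for m in range(first, last + 1)]
        prev = [(harvest_year - 1, m) for m in range(first, 13)]
        curr = [(harvest_year, m) for m in range(1, last + 1)]
        return prev + curr


#: The five crops, keyed by name. Windows: aus Jun-Aug, aman Dec-Jan (wraps),
#: boro Mar-May, potato Feb-Mar, wheat Nov-Mar (wraps).
CROPS: dict[str, CropKind] = {
    "aus": CropKind("aus", Season.KHARIF, (6, 8)),
    "aman": CropKind("aman", Season.RABI, (12, 1)),
    "boro": CropKind("boro", Season.KHARIF, (3, 5)),
    "potato": CropKind("potato", Season.KHARIF, (2, 3)),
    "wheat": CropKind("wheat", Season.RABI, (11, 3)),
}

KEY_COLUMNS = ["district", "year", "crop"]
WEATHER_COLUMNS = [
    "rainfall",
    "temp_max",
    "temp_min",
    "humidity",
    "wind_speed",
    "cloud_coverage",
    "sunshine",
]
PREDICTOR_COLUMNS = WEATHER_COLUMNS + ["area"]
TARGET_COLUMN = "production"
NUMERIC_COLUMNS = PREDICTOR_COLUMNS + [TARGET_COLUMN]
ALL_COLUMNS = KEY_COLUMNS + NUMERIC_COLUMNS

YEAR_RANGE = (1969, 2100)

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A file or frame does not conform to the dataset schema."""


@dataclass
class NormalizationParams:
    """Per-column (min, max) pairs fitted on training data."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for col, (lo, hi) in self.bounds.items():
            if hi < lo:
                raise ValueError(f"max < min for column {col!r}")

    def to_dict(self) -> dict:
        return {c: [lo, hi] for c, (lo, hi) in self.bounds.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls({c: (float(lo), float(hi)) for c, (lo, hi) in d.items()})


@dataclass
class CropDataset:
    """An ordered table of crop records, optionally min-max normalized.

    Missing numeric cells are NaN (never 0). ``norm_params`` is set when
    ``normalization_state == "normalized"`` and stores the per-column
    min/max used, so the transform can be inverted.
    """

    frame: pd.DataFrame
    schema_version: str = SCHEMA_VERSION
    normalization_state: str = "raw"
    norm_params: NormalizationParams | None = None
    n_unparsable: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in ALL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        # normalize column order to schema order; keep any extras at the end
        extras = [c for c in self.frame.columns if c not in ALL_COLUMNS]
        self.frame = self.frame[ALL_COLUMNS + extras].reset_index(drop=True)
        if self.normalization_state not in ("raw", "normalized"):
            raise ValueError(f"bad normalization_state {self.normalization_state!r}")
        if self.normalization_state == "normalized" and self.norm_params is None:
            raise ValueError("normalized dataset requires norm_params")

    def __len__(self) -> int:
        return len(self.frame)

    def copy(self) -> "CropDataset":
        return CropDataset(
            self.frame.copy(),
            schema_version=self.schema_version,
            normalization_state=self.normalization_state,
            norm_params=self.norm_params,
            n_unparsable=self.n_unparsable,
        )

    @property
    def X(self) -> np.ndarray:
        """The 8-column predictor matrix (7 weather + area)."""
        return self.frame[PREDICTOR_COLUMNS].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """The production target vector (tons, or normalized units)."""
        return self.frame[TARGET_COLUMN].to_numpy(dtype=float)

    @classmethod
    def empty(cls) -> "CropDataset":
        frame = pd.DataFrame({c: pd.Series(dtype=object) for c in ALL_COLUMNS})
        return cls(frame)


@dataclass
class ValidationReport:
    n_records: int
    n_missing_by_column: dict[str, int]
    n_unparsable: int
    violations: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    def summary(self) -> str:
        lines = [
            f"records: {self.n_records}",
            f"unparsable cells: {self.n_unparsable}",
            "missing by column: "
            + ", ".join(f"{c}={n}" for c, n in self.n_missing_by_column.items() if n)
            if any(self.n_missing_by_column.values())
            else "missing by column: none",
            f"violations: {self.n_violations}",
        ]
        lines += [f"  row {i}: {rule}" for i, rule in self.violations[:50]]
        if self.n_violations > 50:
            lines.append(f"  ... and {self.n_violations - 50} more")
        return "\n".join(lines)


def _coerce_numeric(series: pd.Series) -> tuple[pd.Series, int]:
    """Parse a column to float; unparsable non-empty cells become NaN, counted."""
    out = pd.to_numeric(series, errors="coerce")
    was_text = series.notna() & (series.astype(str).str.strip() != "")
    n_unparsable = int((was_text & out.isna()).sum())
    return out.astype(float), n_unparsable


def read_dataset(path: str | Path, strict: bool = False) -> CropDataset:
    """Read a crop dataset from CSV.

    Numeric cells that fail to parse become missing (NaN) when
    ``strict=False`` and raise :class:`SchemaError` when ``strict=True``.
    The count of unparsable cells is recorded on ``CropDataset.n_unparsable``
    and surfaced by :func:`validate`. A ``<path>.norm.json`` sidecar, when
    present, restores the normalization state and parameters.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty file: {path}") from None
    missing = [c for c in ALL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s) in {path}: {missing}")

    frame = pd.DataFrame(index=raw.index)
    frame["district"] = raw["district"].astype(str)
    year, n_bad_year = _coerce_numeric(raw["year"])
    frame["year"] = year
    frame["crop"] = raw["crop"].astype(str).str.strip().str.lower()
    n_unparsable = n_bad_year
    for col in NUMERIC_COLUMNS:
        parsed, n_bad = _coerce_numeric(raw[col])
        frame[col] = parsed
        n_unparsable += n_bad
    if strict and n_unparsable:
        raise SchemaError(f"{n_unparsable} unparsable numeric cell(s) in {path}")
    # years are integral where present
    frame["year"] = frame["year"].round().astype("Int64")

    state, params = "raw", None
    sidecar = path.with_name(path.name + ".norm.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            params = NormalizationParams.from_dict(json.load(fh))
        state = "normalized"
    return CropDataset(
        frame,
        normalization_state=state,
        norm_params=params,
        n_unparsable=n_unparsable,
    )


def write_dataset(ds: CropDataset, path: str | Path) -> None:
    """Write a dataset to CSV (missing cells as empty fields).

    Values are written with 17 significant digits so a read round-trip
    reproduces them exactly; a normalized dataset additionally writes a
    ``<path>.norm.json`` sidecar holding its min/max parameters.
    """
    path = Path(path)
    out = ds.frame[ALL_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.17g")
    if ds.normalization_state == "normalized":
        sidecar = path.with_name(path.name + ".norm.json")
        with open(sidecar, "w") as fh:
            json.dump(ds.norm_params.to_dict(), fh, indent=1)


def validate(ds: CropDataset) -> ValidationReport:
    """Check every schema invariant and report violations without mutating.

    Rules: known crop name; year within bounds; 0 <= humidity <= 100;
    temp_min <= temp_max; area >= 0; production >= 0 when present; unique
    (district, year, crop) key. Normalized datasets skip the physical range
    checks (values are on the unit scale by construction).
    """
    f = ds.frame
    violations: list[tuple[int, str]] = []

    for i, crop in f["crop"].items():
        if crop not in CROPS:
            violations.append((int(i), f"unknown crop {crop!r}"))
    year = f["year"]
    for i in f.index[year.notna() & ((year < YEAR_RANGE[0]) | (year > YEAR_RANGE[1]))]:
        violations.append((int(i), f"year {f.at[i, 'year']} outside {YEAR_RANGE}"))

    if ds.normalization_state == "raw":
        hum = f["humidity"]
        for i in f.index[hum.notna() & ((hum < 0) | (hum > 100))]:
            violations.append((int(i), f"humidity {hum[i]} outside [0, 100]"))
        tmin, tmax = f["temp_min"], f["temp_max"]
        both = tmin.notna() & tmax.notna()
        for i in f.index[both & (tmin > tmax)]:
            violations.append((int(i), f"temp_min {tmin[i]} > temp_max {tmax[i]}"))
        for col, rule in [("area", "area < 0"), ("production", "production < 0")]:
            v = f[col]
            for i in f.index[v.notna() & (v < 0)]:
                violations.append((int(i), rule))
        for col in ["wind_speed", "cloud_coverage"]:
            v = f[col]
            for i in f.index[v.notna() & (v < 0)]:
                violations.append((int(i), f"{col} < 0"))

    dup = f.duplicated(subset=KEY_COLUMNS, keep="first")
    for i in f.index[dup]:
        key = tuple(f.loc[i, KEY_COLUMNS])
        violations.append((int(i), f"duplicate key {key}"))

    n_missing = {c: int(f[c].isna().sum()) for c in NUMERIC_COLUMNS}
    violations.sort(key=lambda v: v[0])
    return ValidationReport(
        n_records=len(f),
        n_missing_by_column=n_missing,
        n_unparsable=ds.n_unparsable,
        violations=violations,
    )
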