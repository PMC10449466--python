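"""Synthetic agro-climate dataset generator with stored ground truth.

The real survey data behind this problem are not public, so the generator
emulates their structure: five crops with 1,400 records each (7,000 total),
district x harvest-year keys over 1969-2021, seven seasonal weather
averages, cultivation area in acres, and production in tons.

The generative model is multiplicative-lognormal in yield:

    z_v        = (v - mu_cv) / sigma_cv          (standardized weather)
    log yield  = b0_c + sum_v beta_v * z_v - beta_q * z_tmax^2
                 + u_d + trend * (t - t0) + eps,   eps ~ N(0, noise_sd)
    production = area * exp(log yield)            (tons)

Weather draws are Normal(mu_cv, sigma_cv) truncated to +/- 3 sigma; area is
lognormal per crop; u_d is a per-district effect. The quadratic temp_max
term gives yield a concave response to heat, so tree/neighbour learners and
the linear ridge base have complementary strengths and blending them is
non-trivial. Production is positive by construction. Optional missingness
and duplicate injection exercise the cleaning stages; the realized effects
and noiseless production are returned as :class:`GroundTruth` so recovery
tests can confirm the encoded structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    ALL_COLUMNS,
    CROPS,
    PREDICTOR_COLUMNS,
    WEATHER_COLUMNS,
    CropDataset,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "default_weather_profile",
    "default_area_lognormal",
    "DEFAULT_BETA",
    "generate",
    "inject_missing",
    "inject_duplicates",
    "recover_coefficients",
    "apply_shocks",
]


def default_weather_profile() -> dict[tuple[str, str], tuple[float, float]]:
    """Per-(crop, variable) weather means and sds, 5 x 7 = 35 entries.

    Values are plausible Bangladeshi seasonal climatology for each crop's
    window (monsoon-season aus is wet and cloudy; winter wheat and potato
    are dry and sunny); rainfall in mm, temperatures in deg C, humidity in
    percent, sunshine in hours/day; wind and cloud in their recorded units.
    """
    rows = {
        #          rain      tmax      tmin      humid    wind      cloud      sun
        "aus": [(450, 120), (32, 1.5), (26, 1.0), (85, 4), (8, 2.0), (6, 1.5), (5, 1.0)],
        "aman": [(20, 6), (25, 1.5), (13, 2.0), (75, 5), (4, 1.0), (2, 0.6), (7, 1.0)],
        "boro": [(180, 60), (33, 2.0), (22, 2.0), (75, 5), (7, 2.0), (4, 1.0), (7, 1.0)],
        "potato": [(30, 9), (28, 2.0), (15, 2.0), (70, 5), (5, 1.5), (2, 0.6), (8, 1.5)],
        "wheat": [(25, 8), (26, 2.0), (12, 2.0), (72, 5), (4, 1.0), (2, 0.6), (7, 1.0)],
    }
    return {
        (crop, var): rows[crop][i]
        for crop in CROPS
        for i, var in enumerate(WEATHER_COLUMNS)
    }


def default_area_lognormal() -> dict[str, tuple[float, float]]:
    """Per-crop (mu, sigma) of log cultivated acres.

    Medians around 30k acres for the rice crops and 8-10k for potato and
    wheat, with wide district-to-district spread.
    """
    return {
        "aus": (10.3, 0.6),
        "aman": (10.6, 0.6),
        "boro": (10.5, 0.6),
        "potato": (9.0, 0.7),
        "wheat": (9.2, 0.7),
    }


#: Standardized-weather yield coefficients shared across crops (log scale).
DEFAULT_BETA: dict[str, float] = {
    "rainfall": 0.15,
    "temp_max": 0.05,
    "temp_min": 0.04,
    "humidity": 0.06,
    "wind_speed": -0.04,
    "cloud_coverage": -0.05,
    "sunshine": 0.10,
}

#: Per-crop baseline log yield (tons/acre): rice ~0.45, potato ~3.5, wheat ~0.5.
DEFAULT_INTERCEPT: dict[str, float] = {
    "aus": -0.85,
    "aman": -0.75,
    "boro": -0.60,
    "potato": 1.25,
    "wheat": -0.70,
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_crop: int = 1400
    n_districts: int = 28
    years: tuple[int, int] = (1969, 2021)
    weather_profile: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=default_weather_profile
    )
    area_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=default_area_lognormal
    )
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    beta_quad: float = 0.08
    intercept: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPT))
    district_sd: float = 0.10
    trend_per_year: float = 0.005
    noise_sd: float = 0.10
    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_per_crop < 1:
            raise ValueError("n_per_crop >= 1")
        if self.n_districts < 1:
            raise ValueError("n_districts >= 1")
        if self.years[0] > self.years[1]:
            raise ValueError("years range inverted")
        for rate, name in [(self.missing_rate, "missing_rate"),
                           (self.duplicate_rate, "duplicate_rate")]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for (crop, var), (_, sd) in self.weather_profile.items():
            if sd < 0:
                raise ValueError(f"negative sd for ({crop}, {var})")
        if self.noise_sd < 0 or self.district_sd < 0:
            raise ValueError("sds must be >= 0")


@dataclass
class GroundTruth:
    """The realized generative parameters and per-record noiseless production."""

    district_effects: dict[str, float]
    beta: dict[str, float]
    beta_quad: float
    intercept: dict[str, float]
    trend_per_year: float
    noise_sd: float
    noiseless_production: np.ndarray


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int):
    if sd == 0:
        return np.full(size, mean)
    return stats.truncnorm.rvs(-3, 3, loc=mean, scale=sd, size=size, random_state=rng)


def generate(config: SyntheticConfig | None = None) -> tuple[CropDataset, GroundTruth]:
    """Draw a dataset from the generative model. Deterministic given the seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    districts = [f"district_{i:02d}" for i in range(cfg.n_districts)]
    u = rng.normal(0.0, cfg.district_sd, size=cfg.n_districts)
    y0, y1 = cfg.years

    frames = []
    noiseless_parts = []
    n_years = y1 - y0 + 1
    n_keys = cfg.n_districts * n_years
    if cfg.n_per_crop > n_keys:
        raise ValueError(
            f"n_per_crop={cfg.n_per_crop} exceeds the {n_keys} distinct "
            "(district, year) keys; raise n_districts or widen the year range"
        )
    for crop in CROPS:
        n = cfg.n_per_crop
        # (district, year) drawn without replacement: keys stay unique per crop
        keys = rng.choice(n_keys, size=n, replace=False)
        d_idx = keys // n_years
        year = y0 + keys % n_years
        cols = {}
        z = {}
        for var in WEATHER_COLUMNS:
            mu, sd = cfg.weather_profile[(crop, var)]
            v = _truncated_normal(rng, mu, sd, n)
            cols[var] = v
            z[var] = (v - mu) / sd if sd > 0 else np.zeros(n)
        mu_a, sd_a = cfg.area_lognormal[crop]
        area = rng.lognormal(mu_a, sd_a, size=n)

        log_yield = np.full(n, cfg.intercept[crop], dtype=float)
        for var, b in cfg.beta.items():
            log_yield += b * z[var]
        log_yield -= cfg.beta_quad * z["temp_max"] ** 2
        log_yield += u[d_idx] + cfg.trend_per_year * (year - y0)
        noiseless = area * np.exp(log_yield)
        eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else 0.0
        production = area * np.exp(log_yield + eps)

        frame = pd.DataFrame(
            {
                "district": [districts[i] for i in d_idx],
                "year": year.astype(int),
                "crop": crop,
                **cols,
                "area": area,
                "production": production,
            }
        )
        frames.append(frame)
        noiseless_parts.append(noiseless)

    ds = CropDataset(pd.concat(frames, ignore_index=True)[ALL_COLUMNS])
    truth = GroundTruth(
        district_effects=dict(zip(districts, u.tolist())),
        beta=dict(cfg.beta),
        beta_quad=cfg.beta_quad,
        intercept=dict(cfg.intercept),
        trend_per_year=cfg.trend_per_year,
        noise_sd=cfg.noise_sd,
        noiseless_production=np.concatenate(noiseless_parts),
    )
    if cfg.missing_rate > 0:
        ds = inject_missing(ds, cfg.missing_rate, cfg.seed + 1)
    if cfg.duplicate_rate > 0:
        ds = inject_duplicates(ds, cfg.duplicate_rate, cfg.seed + 2)
    return ds, truth


def inject_missing(ds: CropDataset, rate: float, seed: int) -> CropDataset:
    """Independently blank each predictor cell with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate in [0, 1]")
    out = ds.copy()
    if rate == 0.0 or len(out) == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(PREDICTOR_COLUMNS))) < rate
    block = out.frame[PREDICTOR_COLUMNS].to_numpy(dtype=float)
    block[mask] = np.nan
    out.frame[PREDICTOR_COLUMNS] = block
    return out


def inject_duplicates(ds: CropDataset, rate: float, seed: int) -> CropDataset:
    """Append ceil(rate * n) uniformly chosen rows as exact copies."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate in [0, 1]")
    out = ds.copy()
    n = len(out)
    n_dup = math.ceil(rate * n)
    if n_dup == 0:
        return out
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, n, size=n_dup)
    out.frame = pd.concat(
        [out.frame, out.frame.iloc[picks]], ignore_index=True
    )
    return out


def recover_coefficients(
    ds: CropDataset, config: SyntheticConfig
) -> tuple[dict[str, float], float]:
    """OLS recovery of the yield coefficients from a generated dataset.

    Regresses log(production / area) on the standardized weather z-scores
    (plus the quadratic temp_max term, the year trend, and crop/district
    dummies, so the linear weather coefficients are estimated cleanly).
    Returns the estimated per-variable betas and the quadratic coefficient.
    """
    f = ds.frame
    y = np.log(f["production"].to_numpy(dtype=float) / f["area"].to_numpy(dtype=float))
    n = len(f)
    zcols = []
    for var in WEATHER_COLUMNS:
        z = np.empty(n)
        for crop in CROPS:
            mask = (f["crop"] == crop).to_numpy()
            mu, sd = config.weather_profile[(crop, var)]
            z[mask] = (f.loc[mask, var].to_numpy(dtype=float) - mu) / sd if sd > 0 else 0.0
        zcols.append(z)
    Z = np.column_stack(zcols)
    zq = Z[:, WEATHER_COLUMNS.index("temp_max")] ** 2
    trend = (f["year"].to_numpy(dtype=float) - config.years[0])
    crop_d = pd.get_dummies(f["crop"]).to_numpy(dtype=float)
    dist_d = pd.get_dummies(f["district"], drop_first=True).to_numpy(dtype=float)
    A = np.column_stack([Z, zq[:, None], trend[:, None], crop_d, dist_d])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    beta_hat = {var: float(coef[i]) for i, var in enumerate(WEATHER_COLUMNS)}
    beta_quad_hat = -float(coef[len(WEATHER_COLUMNS)])
    return beta_hat, beta_quad_hat


def apply_shocks(
    ds: CropDataset, shocks: dict[tuple[int, str], float]
) -> CropDataset:
    """Multiply production by per-(year, district) shock factors.

    A robustness hook for disaster scenarios (e.g. a flood year halving
    production in affected districts); not applied by default.
    """
    out = ds.copy()
    f = out.frame
    for (year, district), factor in shocks.items():
        if factor < 0:
            raise ValueError("shock factors must be >= 0")
        mask = (f["year"] == year) & (f["district"] == district)
        f.loc[mask, "production"] *= factor
    return out
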