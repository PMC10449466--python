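# cropcast

Crop-production forecasting and recommendation for district-level
agricultural records, built around a **blending ensemble** of K-nearest
neighbours, random forest and ridge regression (KRR).

## The problem

Agencies and farmers in rice-growing countries plan around forecasts of
how many tons of a crop a district will produce next season, given the
season's weather and the cultivated area. The records involved are tabular:
one row per (district, harvest fiscal year, crop) with seven seasonal
weather averages (rainfall, max/min temperature, humidity, wind speed,
cloud coverage, bright sunshine), cultivation area in acres, and production
in tons. Five crops are modelled — the three Bangladeshi rice seasons (aus,
aman, boro), potato and wheat — each with its own window of responsible
months (aus: Jun–Aug; aman: Dec–Jan; boro: Mar–May; potato: Feb–Mar; wheat:
Nov–Mar). Real records of this kind are not public, so the package ships a
synthetic generator that emulates their structure (5 × 1,400 = 7,000
records over 1969–2021) with stored ground truth.

## The method

**KRR blending.** Split the training rows once into a base-train part and a
blend holdout of fraction `f` (default 0.15, within the 10–15% band typical
for blending). Fit KNN (k=5), random forest (10 trees, seed 42) and ridge
(α=0.01) on base-train; collect their holdout predictions as columns of
`P`; fit the meta-combiner

    w* = argmin_{w ≥ 0, Σw = 1} ‖P w − y_holdout‖²

by exact active-set enumeration over the faces of the 2-simplex. The test
prediction is `ŷ = Σᵢ wᵢ · baseᵢ(x)`. Because every vertex eᵢ is feasible,
the blend's holdout MSE never exceeds the best single base's — a structural
guarantee the test suite checks on every fit. An unconstrained OLS meta
with intercept is available as `meta="ols"`.

**Benchmarks.** Six reference regressors under one fit/predict contract:
linear-kernel SVR (C=100), random forest (20 trees, seed 42), ridge
(α=0.01), gradient-boosted trees (learning rate 0.05), KNN (k=5), and a
naive-Bayes regressor (target discretized into 20 quantile bins, Gaussian
NB posterior over bins, prediction = posterior-weighted bin means).

**Evaluation.** MAE, MSE, RMSE and R² over a three-phase protocol —
80:20, 50:50 and 30:70 train:test ratios, ten seeded trials each — with
per-phase and pooled averages. Model comparison uses the Diebold–Mariano
test on aligned test-error series: `DM = d̄ / √(σ̂²/T)` with
`d_t = L(e_A,t) − L(e_B,t)` and a long-run-variance estimate; one-sided
rejection means the reference model (KRR) is significantly more accurate.
Stars: `*` 1%, `**` 5%, `***` 10%.

**Recommendation.** Given per-crop models, a land unit's features, and
expert minimum-production thresholds τ per (region, season, crop), predict
each season-matching crop's production, keep crops with `P ≥ τ`, rank by
relative margin `(P − τ)/τ`, and recommend the top crop.

## Worked example

```python
import cropcast as cc
from cropcast import preprocess as pp
from cropcast.blend import BlendConfig, fit_krr

ds, _ = cc.generate(cc.SyntheticConfig(n_per_crop=300, seed=11))
norm = pp.minmax_apply(ds, pp.minmax_fit(ds))
model = fit_krr(norm.X, norm.y, BlendConfig(seed=11))
print([round(float(w), 4) for w in model.meta_weights])
print(model.holdout_mse_blend, float(model.holdout_mse_by_base.min()))
```

prints

```
[0.4634, 0.4954, 0.0413]
0.0016815... 0.0022781...
```

— the meta-learner put ~46% weight on KNN, ~50% on the forest and ~4% on
ridge, and the blended holdout MSE (0.00168, on the normalized production
scale) is below the best single base's (0.00228), as the simplex
construction guarantees. The scripts in `examples/` walk through the full
pipeline: generation and cleaning, evaluation, DM comparison, and
recommendation, each printing and explaining its output.

A thin CLI mirrors the stages:

```sh
cropcast simulate -o raw.csv
cropcast preprocess raw.csv -o clean.csv --paper-leakage
cropcast evaluate clean.csv --models ridge,rf,knn,krr --phases 0.8:3 -o report.json
```

## Layout

- `src/cropcast/schema.py` — dataset schema, CSV I/O, validation
- `src/cropcast/preprocess.py` — cleaning, integration, reduction, min–max
- `src/cropcast/models.py` — the six benchmark regressors
- `src/cropcast/blend.py` — the KRR blending ensemble and simplex solver
- `src/cropcast/evaluation.py` — metrics and the phase × trial protocol
- `src/cropcast/dm.py` — Diebold–Mariano test
- `src/cropcast/recommend.py` — threshold-based recommender
- `src/cropcast/simulate.py` — synthetic data generator with ground truth
- `docs/methods.md` — model, assumptions, parameter choices, limitations
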