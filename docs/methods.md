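# Methods

This note records the models, the parameter choices that matter, the
numerical decisions, and what the synthetic experiments do and do not show.

## Data model

The unit of observation is a (district, harvest fiscal year, crop) record
with seven seasonal weather averages, cultivated area (acres) and
production (tons). Each crop has a fixed window of responsible months;
windows that straddle the calendar boundary (aman Dec–Jan, wheat Nov–Mar)
attribute their early months to the year before the harvest fiscal year —
the later month's year names the record. Wind speed and cloud coverage are
carried in their recorded units without conversion. Missing cells are NaN
internally and empty fields in CSV, so 0 is always a value, never a
marker.

## Preprocessing

Cleaning runs in four stages: **coercion** (string stripping,
thousands-separator removal, per-column plausibility bounds, and the
physically forced rule temp_min ≤ temp_max — a violating pair blanks both
temperatures, since neither reading can be trusted); **imputation**
(column-mean over observed values; a `neighbor` option interpolates within
each (district, crop) series ordered by year, falling back to the column
mean at series edges); **reduction** (exact duplicates dropped keeping the
first; "junk" operationalized as rows whose every predictor is missing);
**min–max normalization** x' = (x − min)/(max − min) with stored
parameters and an exact inverse.

The convenience path `clean_pipeline` runs coerce → reduce → impute →
normalize: reduction precedes imputation because a junk row is only
recognizable while its cells are still missing, and duplicate detection is
unaffected (copies impute identically in either order). Min–max parameters
should be fitted on the training split and applied to the test split;
fitting on the full table before splitting leaks the test extremes into
training, so that behaviour is opt-in (`global_fit` / `--paper-leakage`)
for pipelines that normalize the entire dataset up front. Constant columns
map to 0.0 with a warning; out-of-range test values are deliberately not
clipped, since clipping would hide distribution shift.

## Benchmarks

Six regressors share one contract (`RegressorSpec` → `fit` →
`FittedRegressor.predict`): KNN (k = 5 — k is a free choice here; nothing
downstream depends on it), random forest (20 trees, seed 42), ridge
(α = 0.01), linear-kernel SVR (C = 100; gamma is irrelevant under a linear
kernel and ignored with a log message), gradient-boosted regression trees
(learning rate 0.05 — any boosted-tree backend qualifies; oblivious tree
structure is not required), and a naive-Bayes regressor. NB is not natively
a regressor; the construction here discretizes the target into quantile
bins (default 20), fits Gaussian class-conditional densities per feature
with bin-frequency priors, and predicts the posterior-weighted mean of the
bin means. Quantile binning requires at least as many distinct target
values as bins and fails loudly otherwise. Standard families delegate to
scikit-learn; determinism is guaranteed given (spec, data, seed).

## The KRR blending ensemble

Blending, not stacking: one seeded uniform split of the training rows into
base-train and a blend holdout of ⌈f·n⌉ rows (f = 0.15 by default — the top
of the customary 10–15% band, chosen for a more stable meta-fit at small
n; f is constrained so both parts keep ≥ 3 rows, and n ≥ 20 overall). The
bases — KNN k=5, random forest with 10 trees seed 42, ridge α=0.01 — are
fitted on base-train only and never refitted on the full training data;
the holdout exists precisely so the meta-learner sees predictions from
models that did not train on it.

The meta-learner solves least squares over the probability simplex. With
three bases this is solved exactly by enumerating the seven supports
(3 vertices, 3 edges, the interior), reducing each to an unconstrained
`lstsq` via the sum-to-one substitution, discarding infeasible candidates
(any weight < −1e−10), and taking the minimum objective. Ties within a
1e−10 relative tolerance resolve to the earliest candidate in
vertices-first, lowest-index order, so three identical prediction columns
deterministically yield (1, 0, 0). Because all vertices are feasible, the
blend's holdout MSE is ≤ the best base's; the fit asserts this invariant.
A constant-target holdout makes the meta-fit degenerate: the model warns
and falls back to uniform (1/3, 1/3, 1/3) weights. `meta="ols"`
(unconstrained, with intercept) trades the dominance guarantee for a
potentially better fit; the simplex default makes "best combination of the
predictors" literal and testable. Which meta-model the original
formulation used, and whether it carried an intercept, is not determinable;
both options are exposed.

## Evaluation protocol

MAE, MSE, RMSE, R² in their standard forms (1/n Σ|e|, 1/n Σe², √MSE,
1 − SSres/SStot). The protocol runs three phases — 80:20, 50:50, 30:70
train:test, the last read literally as 30% train — with ten trials each.
Trials differ only in the split seed (base seed + trial index); model seeds
stay at their spec values, so trial spread isolates split variance.
Metrics are computed on the normalized target scale (sub-unity MSEs);
inverting the normalization first gives ton-scale errors when needed.
R² requires a non-constant test target and at least 2 points; empty or
mismatched inputs raise rather than return NaN.

## Diebold–Mariano test

For aligned error series, d_t = L(e_A,t) − L(e_B,t) with squared (default)
or absolute loss; σ̂² = γ₀ + 2Σ_{k<h} γ_k with 1/T-normalized
autocovariances (positive semidefinite at h = 1, the convention of the
original construction), floored at γ₀·1e−12; DM = d̄/√(σ̂²/T); one-sided
p = 1 − Φ(DM), so rejection means the reference model (the blend, in the
shipped comparisons) is significantly more accurate. h defaults to 1 —
these are cross-sectional test-set errors, not overlapping multi-step
forecasts. The small-sample option applies the Harvey–Leybourne–Newbold
factor √((T+1−2h+h(h−1)/T)/T) and a t(T−1) reference. A (numerically)
zero-variance differential raises `DegenerateSeriesError` instead of
returning 0: a silent zero would fabricate "no difference" evidence.
Labels: `*` p < 1%, `**` p < 5%, `***` p < 10%.

## Recommender

Candidates are the crops of the queried harvest season (kharif: aus, boro,
potato; rabi: aman, wheat — per the crop table, potato is grouped with the
kharif harvests). The comparison is production against threshold
(P ≥ τ) — production thresholds only, as the recommendation pseudocode
specifies. Ranking uses the relative margin (P − τ)/max(τ, 1e−9): relative
rather than absolute so a rice crop's tonnage does not trivially outrank
wheat's, with the ε guard covering τ = 0. Ties break alphabetically.
Thresholds are institutional inputs (local agriculture offices) and are
treated as opaque nonnegative numbers in whatever unit the models predict.

## Synthetic generator

Per crop, (district, year) keys are drawn uniformly **without replacement**
— a crop has at most one record per district-year, which keeps the
(district, year, crop) key unique as the schema requires. This forces
n_districts × n_years ≥ n_per_crop; the defaults use 28 districts × 53
years = 1,484 keys for 1,400 records per crop (the study area has 64
districts, so 28 is comfortably realistic).

Weather variables are Normal(μ_cv, σ_cv) truncated at ±3σ, with a
climatology table (35 (crop, variable) pairs) in which the monsoon crop is
wet, cloudy and humid and the winter crops dry and sunny. Area is
lognormal per crop (medians ≈ 30k acres for rice, 8–10k for potato and
wheat). Yield is multiplicative-lognormal:

    log yield = β0_c + Σ_v β_v z_v − β_q z_tmax² + u_d + trend·(t − t0) + ε

with z_v the standardized weather, shared coefficients β (rainfall 0.15,
sunshine 0.10, humidity 0.06, temp_max 0.05, temp_min 0.04, wind −0.04,
cloud −0.05), a quadratic heat penalty β_q = 0.08 (concave yield response
to maximum temperature — heat helps up to a point and then hurts), district
effects u_d ~ N(0, 0.10), a productivity trend of 0.5%/year (secular
improvement such as high-yielding-variety adoption), noise sd 0.10, and
per-crop intercepts pinning typical yields (~0.45 t/acre rice, ~3.5
potato, ~0.5 wheat). Production = area · exp(log yield) is positive by
construction. The multiplicative form with a quadratic term gives the
nonparametric bases (KNN, forest) and the linear ridge base complementary
strengths, so the blending weights are informative rather than trivially
degenerate.

The generator emulates structure, not geography: no spatial correlation
between districts, no weather autocorrelation across years, no disaster
shocks by default (an `apply_shocks` hook multiplies production for chosen
(year, district) cells), and no calibration to real national statistics.
Passing tests therefore demonstrate correctness of the machinery —
preprocessing counts, dominance guarantees, statistical calibration — not
predictive skill on real records.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use the full 7,000-record
default draw where structure is the point (shape, dominance sweeps) and
smaller draws elsewhere: 1,000 rows for pipeline-integrity counts, 5,000
low-noise rows (noise sd 0.01) for coefficient recovery, 2,000 replicates
at T = 256 for the DM size check, 1,000 random instances for the
recommender oracle, 3 trials per phase in the demo scripts versus 10 in
the full protocol. Coefficient recovery regresses log(production/area) on
the z-scores plus the quadratic term, trend and crop/district dummies, so
the linear βs are estimated cleanly; the ±3σ truncation perturbs the
z-scale by well under 1%. All randomness flows through
`numpy.random.default_rng` seeds; CSV round-trips write 17 significant
digits so values survive exactly.

## Known limitations

- The NB regressor is one defensible reading of "naive Bayes for a
  continuous target"; other discretization choices would give different
  baselines.
- The simplex solver is specialized to exactly three bases; a larger
  ensemble would need a general QP (the active-set enumeration grows as
  2^k − 1).
- Blending uses a single holdout split; no cross-validated (stacking-style)
  variant is provided, deliberately.
- Thresholds, and therefore recommendations, are only as good as the
  expert values supplied; no uncertainty is propagated into the
  recommendation margin.
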