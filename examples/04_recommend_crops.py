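"""Recommend crops for a land unit from per-crop KRR models and thresholds.

Trains one KRR ensemble per kharif crop on synthetic data, predicts next
season's production for a hypothetical land unit, and filters by expert
minimum-production thresholds. Crops are ranked by relative margin
(prediction - threshold) / threshold; the top-ranked crop is the pick.
"""

import numpy as np

import cropcast as cc
from cropcast import preprocess as pp
from cropcast.blend import BlendConfig, fit_krr
from cropcast.recommend import ThresholdTable, recommend, recommend_report
from cropcast.schema import CROPS
from cropcast.simulate import SyntheticConfig

ds, _ = cc.generate(SyntheticConfig(n_per_crop=300, seed=31))
params = pp.minmax_fit(ds)
norm = pp.minmax_apply(ds, params)

season = "kharif"
crops = [c for c in CROPS if CROPS[c].season.value == season]
models, features = {}, {}
for crop in crops:
    sub = norm.copy()
    sub.frame = norm.frame[norm.frame["crop"] == crop].reset_index(drop=True)
    models[crop] = fit_krr(sub.X, sub.y, BlendConfig(seed=31))
    # query: this land unit's seasonal forecast = that crop's median conditions
    features[crop] = np.median(sub.X, axis=0)

# expert thresholds on the normalized production scale
thresholds = ThresholdTable()
for crop, tau in {"aus": 0.02, "boro": 0.05, "potato": 0.04}.items():
    thresholds.add("demo-district", season, crop, tau)

rec = recommend(models, features, thresholds, "demo-district", season)
text, _ = recommend_report(rec)
print(text)
# Each row shows predicted production vs its threshold; the margin column
# is the relative headroom and decides the ranking.
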