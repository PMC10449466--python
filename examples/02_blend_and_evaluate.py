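"""Fit the KRR blending ensemble and benchmark it with the phase protocol.

Runs all six benchmark regressors plus KRR through the 80:20 / 50:50 /
30:70 phases (3 trials each here to keep the demo quick) and prints the
pooled MAE/MSE/RMSE/R² table. Metrics are on the normalized target scale,
so an MSE of e.g. 0.002 means the typical squared error is 0.2% of the
squared target range.
"""

import cropcast as cc
from cropcast import preprocess as pp
from cropcast.blend import BlendConfig, fit_krr
from cropcast.evaluation import PhaseSpec, run_experiment
from cropcast.models import make_paper_defaults
from cropcast.simulate import SyntheticConfig

ds, _ = cc.generate(SyntheticConfig(n_per_crop=300, seed=11))
norm = pp.minmax_apply(ds, pp.minmax_fit(ds))

model = fit_krr(norm.X, norm.y, BlendConfig(seed=11))
print("KRR meta-weights (knn, rf, ridge):",
      [round(float(w), 4) for w in model.meta_weights])
print(f"holdout MSE: blend {model.holdout_mse_blend:.3g} vs best base "
      f"{model.holdout_mse_by_base.min():.3g}  (blend never loses)")

specs = dict(make_paper_defaults())
specs["krr"] = BlendConfig(seed=11)
phases = (PhaseSpec(0.8, 3), PhaseSpec(0.5, 3), PhaseSpec(0.3, 3))
report = run_experiment(norm, specs, phases, seed=42)
print("\npooled metrics over all phases and trials:")
print(report.table().round(4).to_string())
# The last row is the blending ensemble; its holdout-MSE dominance is a
# structural guarantee, while test-set ranking varies with the draw.
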