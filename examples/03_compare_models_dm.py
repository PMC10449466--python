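"""Diebold-Mariano comparison of benchmark models against the KRR ensemble.

Collects aligned test-set error series from one 80:20 split and tests each
benchmark against KRR. A large positive DM value with stars means the
benchmark's squared-error loss is significantly higher than KRR's
(* = 1%, ** = 5%, *** = 10% one-sided significance).
"""

import cropcast as cc
from cropcast import preprocess as pp
from cropcast.blend import BlendConfig
from cropcast.dm import compare_all
from cropcast.evaluation import collect_test_errors
from cropcast.models import make_paper_defaults
from cropcast.simulate import SyntheticConfig

ds, _ = cc.generate(SyntheticConfig(n_per_crop=300, seed=23))
norm = pp.minmax_apply(ds, pp.minmax_fit(ds))

specs = dict(make_paper_defaults())
specs["krr"] = BlendConfig(seed=23)
errors = collect_test_errors(norm, specs, train_fraction=0.8, seed=5)
table = compare_all(errors, reference="krr", loss="squared")
table["cell"] = [f"{r.dm:.3f}{r.label}" for r in table.itertuples()]
print(table[["model", "cell", "p_one_sided"]].to_string(index=False))
# Positive DM: the row model is less accurate than KRR on this split;
# negative: more accurate. Stars translate the one-sided p-value.
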