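"""Fit and compare stochasticity models on a synthetic study.

Generates one study-sized dataset (16 plots x 18 years) from the published
density-linked model, fits both the density-linked and the constant-variance
variants by maximum likelihood, and ranks them by AIC.  The generating
(density-linked) model should win decisively.
"""

import dlspop as d
from dlspop.io import report_comparison

design, spec_dls, params = d.preset("dls_table2")
_, spec_const, _ = d.preset("constant_table1")

plots = d.generate_study(design, spec_dls, params, seed=7)
data = d.build_lag_dataset(plots, max_lag=1)
print(f"dataset: {data.n_rows} one-step transitions from {len(plots)} plots")

fit_dls = d.fit_ml(data, spec_dls, n_starts=4, seed=0)
fit_const = d.fit_ml(data, spec_const, n_starts=4, seed=0)

table = d.compare_models([fit_dls, fit_const])
print(report_comparison(table).to_string())
print(f"\ndelta-AIC (constant - density-linked): "
      f"{fit_const.aic - fit_dls.aic:.1f}")
print("A large positive margin means the data carry density-linked")
print("stochasticity that a constant-variance model cannot absorb.")
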