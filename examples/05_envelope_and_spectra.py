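"""Diagnostics: prediction envelopes and ensemble power spectra.

Builds a one-step 95% prediction envelope for the density-linked model
(accumulating outcome bins from highest probability, so multimodal outcome
distributions keep disjoint islands), then contrasts low-frequency spectral
power of density-linked vs constant-variance ensembles.
"""

import numpy as np

import dlspop as d

_, spec_dls, params_dls = d.preset("dls_table2")
_, spec_const, params_const = d.preset("constant_table1")

env = d.prediction_envelope(spec_dls, params_dls, n_trials=100,
                            increment=0.1, iters=20_000, seed=1)
print("start cover   95% envelope of next-census cover   disjoint?")
for i, p0 in enumerate(env.grid):
    inside = np.flatnonzero(env.in_envelope[i])
    disjoint = len(inside) < inside.max() - inside.min() + 1
    print(f"  {p0:4.2f}        [{inside.min() / 100:.2f}, {inside.max() / 100:.2f}]"
          f"                       {'yes' if disjoint else 'no'}")
print("At high cover the outcome distribution splits: stay near full cover,")
print("or crash to the post-disturbance state — a bimodal envelope.\n")

inits = np.linspace(0.05, 0.25, 16)
ens_dls = d.simulate(spec_dls, params_dls, inits, T=17, n_trials=484, seed=2)
ens_const = d.simulate(spec_const, params_const, inits, T=17, n_trials=484, seed=2)
s_dls = d.ensemble_spectrum(ens_dls)
s_const = d.ensemble_spectrum(ens_const)
f1 = s_dls.freqs[1]
print(f"mean power at the lowest nonzero frequency ({f1:.3f} cycles/census):")
print(f"  density-linked model: {s_dls.power[1]:.4f} +- {s_dls.se[1]:.4f}")
print(f"  constant variance:    {s_const.power[1]:.4f} +- {s_const.se[1]:.4f}")
print("Stronger low-frequency power = long-period fluctuations, the")
print("signature the constant-variance model fails to reproduce.")
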