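"""Stochastic simulation with density-linked stochasticity.

Simulates 16 replicate plots (matching the study design) under the published
density-linked model: variance declines with density but disturbance
probability rises with it, so trajectories build up over several years and
then crash toward the post-disturbance cover of ~0.39.
"""

import numpy as np

import dlspop as d

_, spec, params = d.preset("dls_table2")
inits = np.linspace(0.05, 0.25, 16)
ens = d.simulate(spec, params, inits, T=18, n_trials=484, seed=42)

print("three of sixteen simulated cover trajectories (19 annual censuses):")
for r in (0, 7, 15):
    print(f"  rep {r:2d}: " + " ".join(f"{p:.2f}" for p in ens.props[r]))

drops = np.diff(ens.props, axis=1) <= -0.3
print(f"\nreplicates with at least one crash of >= 0.30 cover: "
      f"{int(drops.any(axis=1).sum())}/16")
print("Build-up phases punctuated by abrupt crashes reproduce the")
print("quasi-periodic pattern of the field data.")
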