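"""Ensemble selection from a conformer pool.

Simulates scattering from a planted 70/30 mixture of a fully stacked and a
strongly bent trimer conformation, then lets the genetic-algorithm
selector recover the composition from a six-member pool.
"""

import warnings

import numpy as np

from quadflex.ensemble import GAConfig, build_pool, ensemble_stats, \
    gajoe_select

# strongly bent pool members trip a bead-overlap accuracy note from the
# hydrodynamics layer; it has no bearing on curve selection
warnings.filterwarnings("ignore", category=UserWarning)
from quadflex.io import ScatteringProfile
from quadflex.synthetic import JunctionSpec, build_g4_multimer

q = np.linspace(0.006, 0.3, 120)
stacked = build_g4_multimer("212").model
bent = build_g4_multimer("212",
                         junctions=[JunctionSpec("hinge", angle_deg=110)] * 2,
                         seed=2).model
pool_models = [stacked, bent] + [
    build_g4_multimer("221", junctions=[JunctionSpec("hinge",
                                                     angle_deg=a)] * 2,
                      seed=s).model
    for a, s in ((40, 3), (70, 4), (130, 5), (160, 6))]
pool = build_pool(pool_models, q)

i_mix = 100.0 * (0.7 * pool.curves[0] / pool.curves[0][0]
                 + 0.3 * pool.curves[1] / pool.curves[1][0])
sigma = 0.005 * np.sqrt(100.0 * i_mix)
rng = np.random.default_rng(7)
profile = ScatteringProfile(q, i_mix + rng.normal(0, sigma), sigma, "mix")

sol = gajoe_select(pool, profile, GAConfig(repeats=25, max_ensemble=10,
                                           seed=11))
print(f"chi^2 = {sol.chi2:.2f}   scale = {sol.scale:.3f}")
for idx, w in sorted(sol.weights.items()):
    print(f"  member {idx} ({pool.labels[idx]}, Rg {pool.rg_model[idx]:.1f} A)"
          f": weight {w:.2f}")
stats = ensemble_stats(sol, pool)
fractions = {k: float(round(v, 2))
             for k, v in stats["topology_fractions"].items()}
print(f"flexibility index = {stats['flexibility_index']:.2f}   "
      f"topology fractions = {fractions}")

print("\nThe selector concentrates weight on the two planted conformers "
      "near the true\n70/30 split; chi^2 ~ 1 means the weighted ensemble "
      "curve fits within the noise.")
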