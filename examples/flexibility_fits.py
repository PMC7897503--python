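"""Flexibility quantification: swollen-coil fit, global WLC fit, and
bending forces.

Fits the Rg-versus-unit-count series to the swollen Gaussian coil model,
runs the multi-property worm-like-chain global fit on the reconstructed
(Rg, Dt, s20,w) table, and evaluates the force needed to bend each species
through 180 degrees.
"""

from quadflex.datasets import (reference_property_table, swollen_fit_points)
from quadflex.flexibility import (bending_force, fit_swollen,
                                  hydfit_minimize)

n, rg, sigma = swollen_fit_points()
fit = fit_swollen(n, rg, sigma)
print("Swollen Gaussian coil fit of Rg(N):")
print(f"  lp = {fit.lp:.1f} +/- {fit.lp_err:.1f} A   "
      f"v = {fit.v:.3f} +/- {fit.v_err:.3f}   R^2 = {fit.r2:.4f}")

table = reference_property_table()
wlc = hydfit_minimize(table)
print("\nGlobal WLC fit of 12 properties (4 constructs x Rg, Dt, s20,w):")
print(f"  lp = {wlc.lp:.0f} A   M_L = {wlc.ml:.0f} Da/A   d = {wlc.d:.0f} A"
      f"   100*Delta = {wlc.pct_dev:.2f}%")

print("\nForce to bend 180 degrees (semicircular arc):")
for label, lp, length in (("ssDNA", 22.0, 330.0),
                          ("G4 multimer", 34.8, 330.0),
                          ("dsDNA", 550.0, 330.0)):
    print(f"  {label:12s} lp = {lp:5.1f} A, contour 330 A: "
          f"F = {bending_force(lp, length):8.4f} pN")

print("\nBoth routes give lp ~ 33-35 A: the multimer is stiffer than "
      "ssDNA (22 A) but\nfar more pliable than duplex DNA (550 A) - a "
      "semi-flexible chain of rigid G4\nunits joined by deformable "
      "interfaces.")
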