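"""CD spectral decomposition with junction correction.

Simulates strand-normalized CD spectra for 2-, 3- and 4-unit multimers as
sums of hybrid-2 monomer basis spectra plus a junctional interface term,
assigns compositions by exhaustive multiset RSS ranking, derives the
junction spectrum from the assignments, corrects the spectra, and
regresses Delta-eps(290 nm) on the unit count before and after
correction.
"""

from quadflex.cd import (SpectrumCD, builtin_basis, correct_and_regress,
                         derive_junction_spectrum, fit_combinations)
from quadflex.synthetic import simulate_cd

basis = builtin_basis()
comps = {n: ("hybrid-2",) * n for n in (2, 3, 4)}
spectra = simulate_cd(comps, basis, junction_scale=1.0, noise_sd=1.5, seed=3)

print("First-pass multiset assignment (exhaustive RSS over the basis):")
assigned = []
for n_units, spec in spectra.items():
    best = fit_combinations(spec, basis, n_units=n_units)[0]
    print(f"  N={n_units}: {'+'.join(best.multiset)}   RSS = {best.rss:8.1f}"
          f"   (planted: {'+'.join(sorted(comps[n_units]))})")
    assigned.append((spec, best.multiset))

junction = derive_junction_spectrum(assigned, basis)
wl = junction.wavelength
for mark in (240, 260, 285):
    v = junction.mean[abs(wl - mark).argmin()]
    print(f"junction spectrum at {mark} nm: {v:+6.1f} M^-1 cm^-1")

out = correct_and_regress(spectra, junction)
raw, corr = out["regression_raw"], out["regression_corrected"]
print(f"\nDelta-eps(290) vs N   raw:       slope {raw['slope']:6.1f}, "
      f"intercept {raw['intercept']:7.1f}, R^2 {raw['r2']:.4f}")
print(f"Delta-eps(290) vs N   corrected: slope {corr['slope']:6.1f}, "
      f"intercept {corr['intercept']:7.1f}, R^2 {corr['r2']:.4f}")

print("\nSecond-pass RSS on the corrected spectra (junction removed):")
for n_units, spec in out["corrected"].items():
    best = fit_combinations(spec, basis, n_units=n_units)[0]
    print(f"  N={n_units}: {'+'.join(best.multiset)}   RSS = {best.rss:8.1f}")

print("\nThe junction term (positive ~240 nm, negative ~260/285 nm) "
      "depresses each\nspectrum by one interface contribution: the raw "
      "regression shows a negative\nintercept, correction restores it to "
      "~0, and the corrected spectra decompose\ncleanly (RSS drops to the "
      "noise floor).")
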