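# quadflex

Solution-structure analysis of higher-order telomeric G-quadruplex (G4)
multimers — tandem arrays of G4 units folded from human-telomere
d(TTAGGG)_n repeats. The package is for structural biophysicists who
combine SEC-SAXS, analytical ultracentrifugation, size-exclusion
chromatography and circular dichroism to ask how many G4 units a repeat
sequence folds, how stiff the resulting chain is, and which fold
topologies compose it.

Five connected capabilities:

* **Model-free SAXS** — Guinier fitting (I(q) ≈ I₀e^(−q²Rg²/3)),
  dimensionless Kratky classification, and a regularized indirect Fourier
  transform to the pair-distance distribution P(r) with explicit Dmax
  selection.
* **Bead-model scattering & hydrodynamics** — Debye-formula theoretical
  curves, single-model χ² fits with closed-form scaling, and Kirkwood
  double-sum friction giving Dt and s20,w.
* **Ensemble optimization** — a genetic algorithm selects the weighted
  conformer sub-ensemble minimizing χ² = (1/(K−1))Σ[(μI − I_exp)/σ]²,
  with ensemble statistics and a flexibility index.
* **Flexibility models** — the swollen Gaussian coil fit
  Rg = lp·√(N^(2v)/((2v+1)(2v+2))) for the persistence length lp and Flory
  exponent v; a global worm-like-chain fit of (Rg, Dt, s20,w) across
  constructs minimizing the mean-square relative deviation of equivalent
  radii; and bending-force curves F = ½k_BT·lp/R².
* **CD decomposition** — Δε normalization (θ/32982cl), exhaustive
  multiset fitting of monomer topology basis spectra by RSS, derivation of
  the junctional interface spectrum, and the Δε(290 nm)-vs-N regression.

A synthetic-data module generates every input class (discrete worm-like
chains, tandem-G4 bead models with stacked or hinged junctions, noisy SAXS
curves, property tables, CD spectra), so the full pipeline runs and is
tested without any external data. `docs/methods.md` describes the models,
defaults and their rationale.

## Worked example

`examples/flexibility_fits.py` fits both flexibility routes and evaluates
bending forces:

```text
Swollen Gaussian coil fit of Rg(N):
  lp = 34.9 +/- 0.4 A   v = 0.699 +/- 0.019   R^2 = 0.9990

Global WLC fit of 12 properties (4 constructs x Rg, Dt, s20,w):
  lp = 33 A   M_L = 163 Da/A   d = 40 A   100*Delta = 0.00%

Force to bend 180 degrees (semicircular arc):
  ssDNA        lp =  22.0 A, contour 330 A: F =   0.0403 pN
  G4 multimer  lp =  34.8 A, contour 330 A: F =   0.0638 pN
  dsDNA        lp = 550.0 A, contour 330 A: F =   1.0087 pN
```

The two independent routes agree: Rg(N) across the 1–4-unit constructs
gives a persistence length of ~35 Å with Flory exponent ~0.70, and the
12-property worm-like-chain fit lands at lp = 33 Å with mass per unit
length 163 Da/Å — a semi-flexible chain, stiffer than single-stranded DNA
(22 Å) but far more pliable than duplex DNA (550 Å). The force scale says
bending a folded multimer through 180° costs well under 0.1 pN, within
reach of telomere-binding machinery.

The other example scripts each run one capability end to end and print
what the numbers mean: `sequence_properties.py` (construct MW/ε260),
`saxs_profile_analysis.py` (Guinier/Kratky/P(r) of a simulated dimer),
`ensemble_selection.py` (recovering a planted 70/30 conformer mixture),
`cd_decomposition.py` (multiset fitting, junction spectrum, Δε290
regression). A thin CLI (`quadflex seqprops|saxs|bend|flexfit`) exposes
the file-oriented analyses.

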