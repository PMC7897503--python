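# Methods

`quadflex` implements the integrated solution-structure workflow used to
characterize higher-order telomeric G-quadruplex (G4) multimers — tandem
arrays of G4 units folded from human-telomere d(TTAGGG)_n repeats. The
workflow combines model-free SAXS analysis, theoretical scattering of
coarse bead models, genetic-algorithm ensemble selection, global worm-like
chain (WLC) fitting of multi-technique hydrodynamic data, CD spectral
decomposition, and a synthetic-data layer that generates every input class
so the whole pipeline is verifiable without access to the original
experimental files.

## Sequence-derived properties

Molecular weights are average masses of the linear free acid, 5'-OH
oligonucleotide: the sum of nucleoside-monophosphate residue masses
(A 313.21, C 289.18, G 329.21, T 304.20, deoxyinosine 314.19 Da) minus a
61.96 Da terminal-phosphate correction — the convention used by synthesis
vendors, which reproduces the study's construct table at 0.1 kDa.
Extinction coefficients at 260 nm use the Cantor–Warshaw–Tinoco
nearest-neighbor method: the sum of per-dinucleotide coefficients minus the
internal monomer coefficients. Inosine has no standard nearest-neighbor
values; it is substituted by guanine with a warning, so inosine-containing
constructs are approximate by design. Two tabulated reference values (Tel48,
M5) disagree by 100–300 M⁻¹cm⁻¹ with the arithmetic implied by the rest of
the table (repeat increments and single-residue differences); the package
returns the self-consistent nearest-neighbor values.

## Model-free SAXS

The Guinier fit is a weighted linear regression of ln I on q² over the
largest low-q window satisfying q·Rg ≤ 1.3 (community default, iteratively
shrunk from the high-q side; ≥ 8 points). Note that for compact globular
shapes the ln-linear fit at qRg ≤ 1.3 carries an inherent ≈2% Rg
overestimate (truncation bias of the Guinier expansion); the tests document
this rather than hide it.

The pair-distance distribution P(r) is obtained by regularized inversion of
I(q) = 4π ∫ p(r) sinc(qr) dr on a 201-point r-grid: σ-weighted least
squares plus α times a second-difference roughness penalty, endpoint
constraints p(0) = p(Dmax) = 0, and non-negativity (default on, solved by
NNLS). `alpha="auto"` takes the largest α whose log-misfit stays within 30%
of its floor across a 21-point log-spaced grid — an L-curve-corner
surrogate that is deterministic and cheap. Rg and I(0) follow from the
moments Rg² = ∫r²p dr / (2∫p dr), I(0) = 4π∫p dr. Dmax selection is made
explicit (`dmax_scan`): the smallest candidate whose P(r) tail (last 5% of
the grid) stays below 1% of max p and whose misfit is within 10% of the
scan plateau (plus a 0.05 absolute floor so machine-precision misfits on
noise-free data do not destabilize the comparison).

The dimensionless Kratky transform (qRg)²I/I₀ vs qRg is classified
globular / multidomain / flexible by the tail beyond qRg = 2.5: below
0.9·(3/e) → globular; rising above 3/e at the high end → flexible;
otherwise multidomain.

## Theoretical scattering and hydrodynamics of bead models

Scattering of coarse models uses the Debye double sum with
homogeneous-sphere amplitudes f_i(q) = w_i·3(sin x − x cos x)/x³, x = qa_i
(series expansion below x = 0.01 for numerical stability). Single-model
fits minimize χ² = (1/N_p)Σ[(I_exp − c·I_mod)/σ]² with the scale c in
closed form and two bounded nuisance parameters — uniform bead-radius
inflation (0.9–1.1) and an optional 3 Å hydration-shell weight layer
(0–0.1 of bead weight) — standing in for the effective-atomic-radius and
hydration-density parameters of atomistic calculators.

Translational friction uses the Kirkwood approximation for N equal beads,
f = N f₁ / (1 + (f₁/6πηN)·ΣΣ'1/r_ij), f₁ = 6πηā, accurate to a few percent
for compact bead assemblies — sufficient for ranking conformers, which is
its only use here. Dt follows from Stokes–Einstein and s from the Svedberg
relation with partial specific volume v̄ = 0.55 ml/g (G4 DNA). Solvent
defaults are the study's working conditions: 20.0 °C, η = 0.00995 poise,
ρ = 0.9982 g/ml.

## Ensemble selection

A genetic algorithm searches multisets of pool-member curves minimizing
χ² = (1/(K−1))Σ[(μI_ens − I_exp)/σ]², with the scale μ and an optional
constant offset (bounded at 5% of the peak intensity) solved in closed form
per candidate. Chromosomes are fixed-length index vectors (length = max
ensemble size, default 30) with a null gene realizing smaller ensembles;
defaults: population 50, ≤1000 generations with early stop after 100
stagnant generations, per-gene mutation 0.1, one-point crossover 0.5, 10%
elitism, repetition allowed, 200 restarts (all configurable; tests and
examples use 10–25 restarts, which already reach the oracle optimum on the
small pools used). Ensemble statistics report weighted Rg/Dmax
distributions, topology-tag fractions, and a flexibility index defined as
the Shannon entropy of the selected Rg histogram divided by the pool's —
an entropy surrogate for ensemble breadth, deliberately not named after
any external package's metric.

## Flexibility models

* **Swollen Gaussian coil**: Rg = lp·√(N^{2v}/((2v+1)(2v+2))) fitted to
  Rg(N) by weighted nonlinear least squares with v ∈ [0.5, 1]. The N = 2–4
  inputs are the reported P(r)-derived Rg values (19.69, 26.0, 32.7 Å with
  an assumed 2% relative uncertainty, typical of SEC-SAXS reporting); the
  N = 1 monomer value is reconstructed as the reported fit evaluated at
  N = 1 (12.3 Å) because the measured value is not part of the data distributed with
  this package.
* **WLC property theory**: Rg from the Benoit–Doty closed form (with a
  series branch for L/lp < 0.1 to avoid cancellation); Dt as the
  Monte-Carlo average of Kirkwood friction over discrete-WLC configurations
  of touching beads of hydrated diameter d (200 chains, fixed seed —
  common random numbers make the objective smooth and the fit
  deterministic); s by Svedberg. The discrete sampler draws bend angles
  from p(θ) ∝ exp(κcosθ)sinθ with κ calibrated so the tangent correlation
  is exactly e^(−l_seg/lp) at any discretization.
* **Global fit** (`hydfit_minimize`): minimizes the mean-square relative
  deviation Δ² of calculated vs experimental *equivalent radii*
  (a_G = √(5/3)Rg, a_T = kT/6πηDt, a_S from the Svedberg friction), with
  per-property weights, over lp ∈ [20, 100] Å, M_L ∈ [10, 300] Da/Å,
  d ∈ [10, 100] Å: coarse grid then Nelder–Mead refinement, with
  one-at-a-time sensitivity profiles and boundary flags. With 3% property
  noise the single-replicate lp scatters by ≈5 Å (a shallow lp–M_L ridge);
  the median over replicates is unbiased to <5%.
* **Bending force**: F = ½k_BT·lp/R² for a chain bent 180° on a
  semicircular arc. The default geometry reads the length as contour along
  the arc (R = L/π), which reproduces the reference ssDNA value
  (lp = 22 Å, L = 330 Å → 0.040 pN at 293.15 K); an end-to-end mode
  (R = span/2) is provided. Temperature defaults to the study's 20.0 °C.
* **SEC calibration**: linear regression of log₁₀(Rs) on the distribution
  coefficient K_d over ≥3 standards, 95% prediction interval, Dt via
  Stokes–Einstein, and an extrapolation warning outside the standards'
  range.

## CD decomposition

Raw ellipticity converts to molar Δε via Δε = θ/(32982·c·l) (θ in mdeg,
c strand molarity, l cm). Strand-normalized multimer spectra are modeled as
sums of monomer topology basis spectra; `fit_combinations` enumerates all
C(B+N−1, N) multisets of size N over the basis and ranks them by RSS over
a 230–320 nm window (buffer absorbance dominates below 230 nm), or solves
a continuous two-component mixing weight by least squares. The junctional
spectrum is the mean (with min/max envelope) of S_multimer − Σ(assigned
monomers) across constructs; correction subtracts one junction spectrum
per construct by default (a per-junction (N−1)-scaled mode is available —
the right choice is genuinely ambiguous and both are exposed). The
Δε(290 nm)-vs-N regression is reported before and after correction.

The packaged basis is a Gaussian-band parameterization (synthetic, not
measured): hybrid folds with the main positive band near 290 nm, a
268 nm shoulder (hybrid-2), a 235–237 nm trough, and antiparallel-type
spectra with a 265 nm trough. Amplitudes put the per-strand Δε(290) of the
hybrid monomers near 1.3×10² M⁻¹cm⁻¹. Measured basis spectra can be
supplied as a `BasisSet` to replace it.

## Synthetic data

The generators define the study conditions used by the tests:

* Discrete WLC chains with the calibrated bend-angle law above.
* Tandem G4 bead models: each unit is a 7-bead cluster (central bead, two
  axial, four equatorial; bead radius 6 Å) approximating a 24 Å × 21 Å
  cylinder. Stacked junctions place units coaxially with a 16 Å gap —
  calibrated once so the 2-unit stacked model reproduces the measured
  dimer Rg ≈ 19.7 Å, then frozen. Hinged junctions bend the axis
  (von-Mises-like distribution, or a fixed angle) *and* release the
  three-nucleotide TTA linker, adding 20 Å of separation — so an
  unstacked junction is both bent and longer, and stacked conformers
  sediment faster than hinged ones, as the hydrodynamic data require.
* SAXS curves with counting-like noise σ(q) = b·√(I + c_bg).
* Property tables from the WLC theory times (1 + N(0, cv)), cv = 0.03 by
  default, weights ∝ 1/cv².
* CD spectra as basis sums plus an optional junction term (positive band
  at 240 nm, negative at 260/285 nm) and additive noise.

What the synthetic layer does not emulate: inter-particle interference and
buffer-subtraction artifacts in SAXS, concentration dependence of s,
instrument line shapes in CD, and conformer pools from molecular dynamics.
Tests passing on synthetic data therefore validate the estimators and
their statistical behavior, not those experimental systematics.

The reconstructed 12-property reference table
(`datasets.reference_property_table`) is generated by the package's own
WLC theory at the reported optimum (lp = 33 Å, M_L = 163 Da/Å,
d = 40 Å), because the per-construct experimental values are in
material not distributed with this package; the theory reproduces the reported
s20,w anchor of the 3-unit construct (3.46 S) to about 5%, commensurate
with the ~4% mean deviation reported for the original global fit.

## Numerical choices and problem sizes

Fixed seeds everywhere a generator or Monte-Carlo average is involved; the
suite is fully reproducible. Test problem sizes are chosen for depth per
CPU-second: pools of 6–8 conformers, 100–250 q-points, 10–25 GA restarts,
12 recovery replicates, 200-chain friction averages. Degenerate inputs
(empty models, all-zero P(r), σ ≤ 0, sub-bead chains, boundary optima) are
rejected or flagged rather than silently accepted.

## Known limitations

Kirkwood friction underestimates hydrodynamic interaction for strongly
overlapping beads (warned); the Debye calculator has no solvent-excluded
volume or explicit hydration layer beyond the coarse shell option; the
P(r) auto-α is a surrogate for a full L-curve curvature analysis; the
GA explores small pools exhaustively in effect but is heuristic on large
pools; and the CD basis is a parameterization whose absolute amplitudes
matter only relative to each other.
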