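"""Circular dichroism decomposition of G-quadruplex multimer spectra.

Strand-normalized CD spectra of tandem G4 multimers are, to first order,
sums of their constituent monomer topology spectra.  This module converts
raw ellipticity to molar Delta-epsilon, composes theoretical multimer
spectra from a monomer basis, ranks all basis multisets by residual sum of
squares against a target spectrum, derives the residual "junctional"
spectrum attributable to G4-G4 interfaces, and regresses Delta-eps(290 nm)
against the number of G4 units before/after junction correction.

The built-in basis is a Gaussian-band parameterization with the
qualitative features of hybrid-type telomeric G4 spectra (main positive
band near 290 nm, shoulder near 268 nm, trough near 235 nm); measured
basis spectra can be supplied instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpectrumCD",
    "BasisSet",
    "CombinationFit",
    "JunctionSpectrum",
    "mdeg_to_deltaeps",
    "builtin_basis",
    "compose_spectrum",
    "fit_combinations",
    "derive_junction_spectrum",
    "correct_and_regress",
]

# mdeg -> molar Delta-epsilon conversion constant (theta / (32982 c l)).
MDEG_CONVERSION = 32982.0

DEFAULT_FIT_WINDOW = (230.0, 320.0)


@dataclass
class SpectrumCD:
    """A CD spectrum on an ascending wavelength grid (nm).

    ``values`` are molar Delta-epsilon (M^-1 cm^-1) when ``units ==
    'deltaeps'``, else raw ellipticity in mdeg with the conversion
    metadata (strand molarity c, path length l) attached.
    """

    wavelength: np.ndarray
    values: np.ndarray
    units: str = "deltaeps"
    c_molar: float | None = None
    path_cm: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength.shape != self.values.shape:
            raise ValueError("wavelength and values must match in length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength grid must be ascending")
        if self.units not in ("deltaeps", "mdeg"):
            raise ValueError(f"unknown units {self.units!r}")

    def to_deltaeps(self) -> "SpectrumCD":
        if self.units == "deltaeps":
            return self
        return SpectrumCD(self.wavelength,
                          mdeg_to_deltaeps(self.values, self.c_molar,
                                           self.path_cm),
                          "deltaeps", label=self.label)

    def at(self, wavelength: float) -> float:
        """Value at the given wavelength (nearest grid point, with warning
        if off-grid)."""
        j = int(np.argmin(np.abs(self.wavelength - wavelength)))
        if abs(self.wavelength[j] - wavelength) > 0.51:
            warnings.warn(f"{wavelength} nm not on grid; using nearest "
                          f"{self.wavelength[j]} nm", stacklevel=2)
        return float(self.values[j])


@dataclass
class BasisSet:
    """Named monomer topology spectra (Delta-eps per strand) on one grid."""

    wavelength: np.ndarray
    spectra: dict  # name -> np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        for name, v in self.spectra.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.wavelength.shape:
                raise ValueError(f"basis {name!r} not on the common grid")
            self.spectra[name] = v
        if len(self.spectra) < 1:
            raise ValueError("basis must contain at least one spectrum")

    @property
    def names(self) -> list:
        return list(self.spectra)


@dataclass
class CombinationFit:
    multiset: tuple
    rss: float
    rank: int
    weights: tuple | None = None  # set in ratio mode


@dataclass
class JunctionSpectrum:
    wavelength: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    n_constructs: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------

def mdeg_to_deltaeps(theta, c_molar: float, path_cm: float):
    """Delta-eps = theta / (32982 * c * l); theta in mdeg, c in mol/l,
    l in cm."""
    if c_molar is None or path_cm is None:
        raise ValueError("strand molarity and path length are required")
    if c_molar <= 0 or path_cm <= 0:
        raise ValueError("c and l must be positive")
    return np.asarray(theta, dtype=float) / (MDEG_CONVERSION * c_molar
                                             * path_cm)


# ---------------------------------------------------------------------------
# built-in basis
# ---------------------------------------------------------------------------

# Gaussian bands (center nm, sigma nm, amplitude in Delta-eps) per topology.
# Amplitudes are chosen so the per-strand Delta-eps(290) of the hybrid
# monomers averages ~1.3e2 M^-1 cm^-1 and the shapes carry the field's
# qualitative signatures; they are a parameterization, not measured data.
_BASIS_BANDS = {
    "hybrid-1": [(291.0, 11.0, 155.0), (255.0, 12.0, 35.0),
                 (237.0, 8.0, -60.0)],
    "hybrid-2": [(290.0, 11.0, 95.0), (268.0, 9.0, 55.0),
                 (250.0, 10.0, 20.0), (236.0, 8.0, -55.0)],
    "hybrid-3": [(293.0, 10.0, 120.0), (265.0, 9.0, -35.0),
                 (245.0, 8.0, 25.0)],
    "basket": [(295.0, 10.0, 90.0), (265.0, 9.0, -70.0),
               (245.0, 8.0, 55.0)],
}


def _gaussian_sum(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, s, a in bands:
        out += a * np.exp(-0.5 * ((wl - c) / s) ** 2)
    return out


def builtin_basis(wavelength=None) -> BasisSet:
    """The packaged synthetic monomer basis (hybrid-1/-2/-3, basket)."""
    wl = (np.arange(220.0, 321.0)
          if wavelength is None else np.asarray(wavelength, dtype=float))
    return BasisSet(wl, {name: _gaussian_sum(wl, bands)
                         for name, bands in _BASIS_BANDS.items()})


# ---------------------------------------------------------------------------
# composition and decomposition
# ---------------------------------------------------------------------------

def _resolve_on_grid(target: SpectrumCD, basis: BasisSet):
    t = target.to_deltaeps()
    if (t.wavelength.shape == basis.wavelength.shape
            and np.allclose(t.wavelength, basis.wavelength)):
        return t.values, basis.wavelength
    warnings.warn("target and basis grids differ; interpolating target onto "
                  "the basis grid", stacklevel=3)
    vals = np.interp(basis.wavelength, t.wavelength, t.values)
    return vals, basis.wavelength


def compose_spectrum(composition, basis: BasisSet,
                     n_units: int | None = None) -> SpectrumCD:
    """Theoretical multimer spectrum from a monomer basis.

    ``composition`` is either a multiset (iterable of basis names, one per
    G4 unit; strand-normalized additivity: the sum of the monomer spectra)
    or a weight mapping name -> w with sum(w) = 1, in which case
    ``n_units`` scales the weighted mean: N * sum_k w_k basis_k.
    """
    if isinstance(composition, dict):
        w = {k: float(v) for k, v in composition.items()}
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be >= 0")
        tot = sum(w.values())
        if not np.isclose(tot, 1.0):
            raise ValueError("ratio-mode weights must sum to 1")
        if n_units is None:
            raise ValueError("n_units required for ratio-mode composition")
        vals = n_units * sum(wk * basis.spectra[k] for k, wk in w.items())
        label = f"{n_units}x(" + "+".join(f"{v:g}*{k}"
                                          for k, v in w.items()) + ")"
    else:
        names = list(composition)
        if not names:
            raise ValueError("empty composition")
        vals = sum(basis.spectra[k] for k in names)
        label = "+".join(names)
    return SpectrumCD(basis.wavelength, np.asarray(vals, dtype=float),
                      "deltaeps", label=label)


def fit_combinations(target: SpectrumCD, basis: BasisSet, n_units: int,
                     mode: str = "enum",
                     window: tuple = DEFAULT_FIT_WINDOW,
                     ratio_names: tuple | None = None) -> list[CombinationFit]:
    """Rank basis compositions against a target spectrum by RSS.

    ``enum`` mode enumerates every multiset of size ``n_units`` over the
    basis (C(B + N - 1, N) candidates) and ranks them by residual sum of
    squares over the fit window.  ``ratio`` mode solves the continuous 1-D
    mixing weight between two basis spectra by least squares.
    """
    if len(basis.spectra) < 1:
        raise ValueError("basis must contain at least one spectrum")
    t_vals, wl = _resolve_on_grid(target, basis)
    sel = (wl >= window[0]) & (wl <= window[1])
    results = []
    if mode == "enum":
        for ms in itertools.combinations_with_replacement(
                sorted(basis.names), n_units):
            model = sum(basis.spectra[k] for k in ms)
            rss = float(np.sum((t_vals[sel] - model[sel]) ** 2))
            results.append(CombinationFit(multiset=ms, rss=rss, rank=-1))
    elif mode == "ratio":
        names = ratio_names or tuple(basis.names[:2])
        if len(names) != 2:
            raise ValueError("ratio mode needs exactly two basis names")
        b1 = basis.spectra[names[0]][sel]
        b2 = basis.spectra[names[1]][sel]
        y = t_vals[sel] / n_units
        # y ~ w b1 + (1-w) b2  ->  (y - b2) ~ w (b1 - b2)
        db = b1 - b2
        w = float(np.dot(y - b2, db) / np.dot(db, db))
        w = min(max(w, 0.0), 1.0)
        model = n_units * (w * b1 + (1 - w) * b2)
        rss = float(np.sum((t_vals[sel] - model) ** 2))
        results.append(CombinationFit(multiset=names, rss=rss, rank=1,
                                      weights=(w, 1 - w)))
        return results
    else:
        raise ValueError(f"unknown mode {mode!r}")
    results.sort(key=lambda r: r.rss)
    for i, r in enumerate(results, 1):
        r.rank = i
    return results


def derive_junction_spectrum(assigned_spectra, basis: BasisSet
                             ) -> JunctionSpectrum:
    """Residual junction spectrum from multimer spectra with assigned
    compositions.

    ``assigned_spectra`` is a list of (SpectrumCD, multiset) pairs; per
    construct J = S_multimer - sum(monomer basis spectra of the multiset).
    Returns the pointwise mean and min/max envelope.  A single construct
    yields a degenerate (zero-width) envelope, flagged.
    """
    if not assigned_spectra:
        raise ValueError("need at least one assigned spectrum")
    diffs = []
    for spec, multiset in assigned_spectra:
        vals, wl = _resolve_on_grid(spec, basis)
        model = compose_spectrum(multiset, basis).values
        diffs.append(vals - model)
    diffs = np.array(diffs)
    degenerate = diffs.shape[0] < 2
    if degenerate:
        warnings.warn("single construct: junction envelope is degenerate",
                      stacklevel=2)
    return JunctionSpectrum(wavelength=basis.wavelength,
                            mean=diffs.mean(axis=0),
                            lo=diffs.min(axis=0), hi=diffs.max(axis=0),
                            n_constructs=diffs.shape[0],
                            degenerate=degenerate)


def correct_and_regress(spectra_by_n: dict, junction: JunctionSpectrum,
                        wavelength: float = 290.0,
                        junction_mode: str = "unit") -> dict:
    """Junction-correct multimer spectra and regress Delta-eps(290) on N.

    ``spectra_by_n`` maps the G4-unit count N (>= 3 distinct values) to a
    SpectrumCD.  ``junction_mode='unit'`` subtracts one junction spectrum
    per construct; ``'per-junction'`` scales the correction by (N - 1).
    Returns corrected spectra, and slope/intercept/R^2 of the weighted
    linear regressions before and after correction.
    """
    if len(spectra_by_n) < 3:
        raise ValueError("need spectra for >= 3 distinct unit counts")
    if junction_mode not in ("unit", "per-junction"):
        raise ValueError(f"unknown junction mode {junction_mode!r}")
    corrected = {}
    raw_vals, corr_vals, ns = [], [], []
    for n, spec in sorted(spectra_by_n.items()):
        s = spec.to_deltaeps()
        jvals = np.interp(s.wavelength, junction.wavelength, junction.mean)
        scale = 1.0 if junction_mode == "unit" else (n - 1)
        cs = SpectrumCD(s.wavelength, s.values - scale * jvals, "deltaeps",
                        label=f"{s.label}_corr")
        corrected[n] = cs
        ns.append(float(n))
        raw_vals.append(s.at(wavelength))
        corr_vals.append(cs.at(wavelength))
    ns = np.array(ns)

    def regress(y):
        res = stats.linregress(ns, np.array(y))
        return {"slope": float(res.slope), "intercept": float(res.intercept),
                "r2": float(res.rvalue ** 2)}

    return {"corrected": corrected,
            "regression_raw": regress(raw_vals),
            "regression_corrected": regress(corr_vals),
            "n": ns, "raw_values": np.array(raw_vals),
            "corrected_values": np.array(corr_vals)}
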