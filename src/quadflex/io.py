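"""Readers, writers and sequence-derived construct metadata.

The pipeline touches four external data classes: 1-D SAXS profiles
(3-column ASCII ``.dat``), coordinate models (PDB ATOM/HETATM subset or
plain bead lists), per-construct hydrodynamic property tables
(delimited text), and DNA sequences.  Everything is validated on read;
arrays are plain float64 numpy arrays.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScatteringProfile",
    "OligoRecord",
    "PropertyRecord",
    "CoordinateModel",
    "read_scattering_dat",
    "write_scattering_dat",
    "read_property_table",
    "read_coordinates",
    "oligo_mw",
    "oligo_eps260",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ScatteringProfile:
    """One-dimensional scattering curve I(q) with 1-sigma uncertainties.

    q is the momentum transfer in inverse Angstrom, strictly increasing and
    positive.  ``sigma`` may be None for 2-column files (flagged by
    ``has_sigma``).
    """

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.i.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q in length")
        dq = np.diff(self.q)
        if np.any(dq <= 0):
            j = int(np.argmax(dq <= 0))
            raise ValueError(
                f"q must be strictly increasing; violation at row {j + 1} "
                f"(q[{j}]={self.q[j]:.6g} >= q[{j + 1}]={self.q[j + 1]:.6g})"
            )
        if np.any(self.q <= 0):
            raise ValueError("q values must be positive")
        if self.sigma is not None and np.any(self.sigma <= 0):
            raise ValueError("sigma values must be positive where present")

    @property
    def has_sigma(self) -> bool:
        return self.sigma is not None

    def __len__(self) -> int:
        return self.q.size

    def scaled(self, factor: float) -> "ScatteringProfile":
        """Return a copy with I (and sigma) multiplied by ``factor``."""
        return ScatteringProfile(
            self.q,
            self.i * factor,
            None if self.sigma is None else self.sigma * factor,
            self.label,
        )


@dataclass
class OligoRecord:
    """A DNA oligonucleotide with sequence-derived properties."""

    name: str
    sequence: str
    mw_kda: float
    eps260: float


@dataclass
class PropertyRecord:
    """Per-construct hydrodynamic/scattering observables for the global WLC fit.

    Units: mw in Da, s20w in Svedberg (1e-13 s), dt in cm^2/s, rg in Angstrom.
    ``weights`` maps property name -> dimensionless weight w_Y (default 1).
    """

    name: str
    mw: float
    s20w: float | None = None
    dt: float | None = None
    rg: float | None = None
    weights: dict = field(default_factory=dict)

    PROPERTIES = ("rg", "dt", "s20w")

    def __post_init__(self) -> None:
        if self.mw is None or not self.mw > 0:
            raise ValueError(f"record {self.name!r}: MW must be positive")
        for p in self.PROPERTIES:
            v = getattr(self, p)
            if v is not None and not v > 0:
                raise ValueError(f"record {self.name!r}: {p} must be positive")
        if not self.present_properties():
            raise ValueError(f"record {self.name!r}: no property present")
        for p in self.present_properties():
            self.weights.setdefault(p, 1.0)

    def present_properties(self) -> tuple:
        return tuple(p for p in self.PROPERTIES if getattr(self, p) is not None)


@dataclass
class CoordinateModel:
    """Coarse bead (or atom) model: positions, scattering weights, radii.

    ``xyz`` is (n, 3) in Angstrom; ``f`` effective electrons per site;
    ``a`` hydrodynamic/form-factor radii in Angstrom.
    """

    xyz: np.ndarray
    f: np.ndarray
    a: np.ndarray
    label: str = ""
    topology_tag: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        self.f = np.asarray(self.f, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        n = self.xyz.shape[0]
        if n < 1 or self.xyz.shape[1] != 3:
            raise ValueError("model requires >=1 site with (x, y, z)")
        if self.f.shape != (n,) or self.a.shape != (n,):
            raise ValueError("f and a must have one entry per site")
        if np.any(self.a <= 0):
            raise ValueError("site radii must be positive")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("site coordinates must be finite")

    @property
    def n_sites(self) -> int:
        return self.xyz.shape[0]

    def translated(self, shift) -> "CoordinateModel":
        return CoordinateModel(self.xyz + np.asarray(shift, dtype=float),
                               self.f, self.a, self.label, self.topology_tag)

    def rotated(self, rotmat) -> "CoordinateModel":
        R = np.asarray(rotmat, dtype=float)
        return CoordinateModel(self.xyz @ R.T, self.f, self.a,
                               self.label, self.topology_tag)

    def rg(self) -> float:
        """Mass(weight)-weighted radius of gyration of the site distribution.

        Includes the parallel-axis contribution (3/5)a^2 of each homogeneous
        sphere so that it matches the Rg implied by the Debye curve.
        """
        w = self.f / self.f.sum()
        com = w @ self.xyz
        d2 = np.sum((self.xyz - com) ** 2, axis=1)
        return float(np.sqrt(w @ (d2 + 0.6 * self.a ** 2)))

    def dmax(self) -> float:
        """Maximum intra-particle distance including bead radii."""
        d = np.linalg.norm(self.xyz[:, None, :] - self.xyz[None, :, :], axis=-1)
        ij = np.unravel_index(np.argmax(d), d.shape)
        return float(d[ij] + self.a[ij[0]] + self.a[ij[1]])


# ---------------------------------------------------------------------------
# SAXS .dat io
# ---------------------------------------------------------------------------

def read_scattering_dat(path, label: str | None = None,
                        q_unit: str = "invA") -> ScatteringProfile:
    """Read a 2/3-column ASCII SAXS profile (q, I[, sigma]).

    Comment lines (``#``) and non-numeric header lines are skipped.
    ``q_unit='invnm'`` converts nm^-1 input to A^-1 (x 0.1).
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                continue  # header / trailer text
            if len(vals) >= 2:
                rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no numeric data rows found")
    if len(rows) < 10:
        raise ValueError(f"{path}: only {len(rows)} data rows; expected >= 10")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q = arr[:, 0]
    if q_unit == "invnm":
        q = q * 0.1
    elif q_unit != "invA":
        raise ValueError(f"unknown q unit {q_unit!r}")
    sigma = arr[:, 2] if ncol >= 3 else None
    if sigma is None:
        warnings.warn(f"{path}: 2-column file, no uncertainties", stacklevel=2)
    return ScatteringProfile(q, arr[:, 1], sigma,
                             label if label is not None else path.stem)


def write_scattering_dat(profile: ScatteringProfile, path,
                         header: str = "") -> None:
    """Write a profile as full-precision 3-column (or 2-column) ASCII."""
    with open(path, "w") as fh:
        if header:
            for ln in header.splitlines():
                fh.write(f"# {ln}\n")
        fh.write("# q(1/A) I sigma\n" if profile.has_sigma else "# q(1/A) I\n")
        cols = [profile.q, profile.i]
        if profile.has_sigma:
            cols.append(profile.sigma)
        for row in zip(*cols):
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# property tables
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "name": ("name", "construct", "sample", "id"),
    "mw": ("mw", "mw_da", "molecular_weight"),
    "s20w": ("s20w", "s20,w", "s", "s_20w"),
    "dt": ("dt", "d_t", "diffusion"),
    "rg": ("rg", "r_g", "radius_of_gyration"),
}


def _find_column(df: pd.DataFrame, key: str) -> str | None:
    lower = {c.lower().strip(): c for c in df.columns}
    for alias in _COLUMN_ALIASES[key]:
        if alias in lower:
            return lower[alias]
    return None


def read_property_table(path_or_buf) -> list[PropertyRecord]:
    """Read a delimited table of per-construct properties.

    Recognized columns (case-insensitive): name, mw [Da], s20w [S],
    dt [cm^2/s], rg [A], and optional per-property weight columns
    ``w_rg``/``w_dt``/``w_s20w``.  Missing cells yield absent properties.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python",
                     comment="#", skipinitialspace=True)
    cols = {k: _find_column(df, k) for k in _COLUMN_ALIASES}
    if cols["mw"] is None:
        raise ValueError("property table requires an MW column")
    if all(cols[p] is None for p in PropertyRecord.PROPERTIES):
        raise ValueError("no recognizable property column (rg/dt/s20w)")
    lower = {c.lower().strip(): c for c in df.columns}
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        weights = {}
        for p in PropertyRecord.PROPERTIES:
            col = cols[p]
            v = row[col] if col is not None else np.nan
            if pd.notna(v):
                if float(v) <= 0:
                    raise ValueError(
                        f"row {idx + 1} ({row.get(cols['name'], '?')}): "
                        f"{p} must be positive, got {v}")
                kwargs[p] = float(v)
                wcol = lower.get(f"w_{p}")
                if wcol is not None and pd.notna(row[wcol]):
                    weights[p] = float(row[wcol])
        name = (str(row[cols["name"]]) if cols["name"] is not None
                else f"row{idx + 1}")
        records.append(PropertyRecord(name=name, mw=float(row[cols["mw"]]),
                                      weights=weights, **kwargs))
    return records


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def read_coordinates(path, label: str | None = None) -> CoordinateModel:
    """Read a coordinate model: PDB ATOM/HETATM records or a 5-column bead list.

    PDB files are parsed with gemmi; per-atom scattering weights are atomic
    electron counts and radii default to 1.7 A (generic heavy-atom sphere).
    Bead lists are whitespace-delimited ``x y z f a`` rows.
    """
    path = Path(path)
    text = path.read_text()
    if any(line[:6] in ("ATOM  ", "HETATM") for line in text.splitlines()):
        return _read_pdb(path, label)
    return _read_bead_list(path, text, label)


def _read_pdb(path: Path, label: str | None) -> CoordinateModel:
    import gemmi

    st = gemmi.read_pdb(str(path))
    xyz, f = [], []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    f.append(atom.element.atomic_number)
        break  # first model only
    if not xyz:
        raise ValueError(f"{path}: no ATOM/HETATM sites parsed")
    n = len(xyz)
    return CoordinateModel(np.array(xyz), np.array(f, dtype=float),
                           np.full(n, 1.7),
                           label if label is not None else path.stem)


def _read_bead_list(path: Path, text: str, label: str | None) -> CoordinateModel:
    rows = []
    for lineno, line in enumerate(text.splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        try:
            vals = [float(x) for x in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinate field "
                             f"in {s!r}") from exc
        if len(vals) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns "
                             f"(x y z f a), got {len(vals)}")
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no parsable sites")
    arr = np.array(rows)
    return CoordinateModel(arr[:, :3], arr[:, 3], arr[:, 4],
                           label if label is not None else path.stem)


def write_bead_list(model: CoordinateModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z f a\n")
        for p, f, a in zip(model.xyz, model.f, model.a):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {f:.6f} {a:.6f}\n")


# ---------------------------------------------------------------------------
# sequence-derived properties
# ---------------------------------------------------------------------------

# Average residue (nucleoside monophosphate) masses in the DNA chain, Da.
# Linear free acid, 5'-OH convention: total = sum(residues) - 61.96
# (removal of one terminal phosphate HPO3 + addition of H/OH ends).
_RESIDUE_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.20,
    "I": 314.19,  # deoxyinosine: dG residue minus NH (15.02)
}
_TERMINAL_CORRECTION = 61.96

# Cantor-Warshaw-Tinoco nearest-neighbor extinction coefficients at 260 nm.
# Dimer values are per-dinucleotide (M^-1 cm^-1); eps(seq) =
# sum(dimers) - sum(internal monomers).
_NN_DIMER = {
    "AA": 27400, "AC": 21200, "AG": 25000, "AT": 22800,
    "CA": 21200, "CC": 14600, "CG": 18000, "CT": 15200,
    "GA": 25200, "GC": 17600, "GG": 21600, "GT": 20000,
    "TA": 23400, "TC": 16200, "TG": 19000, "TT": 16800,
}
_MONOMER_EPS = {"A": 15400, "C": 7400, "G": 11500, "T": 8700}


def _clean_sequence(sequence: str) -> str:
    """Upper-case and strip placeholder characters ('_' = removed base)."""
    seq = sequence.upper().replace("_", "").replace(" ", "")
    bad = set(seq) - set("ACGTI")
    if bad:
        raise ValueError(f"unknown residue letter(s): {sorted(bad)}")
    return seq


def oligo_mw(sequence: str) -> float:
    """Average molecular weight of a linear free-acid 5'-OH DNA oligo, in kDa.

    Sum of residue monophosphate masses minus the 61.96 Da terminal-phosphate
    correction.  Matches the vendor convention used for synthetic oligos.
    """
    seq = _clean_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    da = sum(_RESIDUE_MASS[c] for c in seq) - _TERMINAL_CORRECTION
    return da / 1000.0


def oligo_eps260(sequence: str) -> float:
    """Nearest-neighbor molar extinction coefficient at 260 nm (M^-1 cm^-1).

    Inosine has no standard nearest-neighbor coefficients; it is treated as
    guanine (with a warning), so values for inosine-containing constructs are
    approximate.
    """
    seq = _clean_sequence(sequence)
    if not seq:
        raise ValueError("empty sequence")
    if "I" in seq:
        warnings.warn("inosine approximated by guanine nearest-neighbor "
                      "coefficients", stacklevel=2)
        seq = seq.replace("I", "G")
    if len(seq) == 1:
        warnings.warn("single-residue sequence: returning monomer epsilon",
                      stacklevel=2)
        return float(_MONOMER_EPS[seq])
    dimers = sum(_NN_DIMER[seq[i:i + 2]] for i in range(len(seq) - 1))
    internal = sum(_MONOMER_EPS[c] for c in seq[1:-1])
    return float(dimers - internal)


def oligo_record(name: str, sequence: str) -> OligoRecord:
    """Bundle a sequence with its derived MW (kDa) and eps260."""
    return OligoRecord(name=name, sequence=sequence,
                       mw_kda=round(oligo_mw(sequence), 1),
                       eps260=oligo_eps260(sequence))
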