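"""Synthetic-data generators for every input class the pipeline consumes.

The generators emulate the statistical structure the analyses assume:
discrete worm-like chains of stated persistence length; tandem G4 bead
models (rigid ~20-25 A cylinder-like units linked by stacked or hinged
junctions); SAXS curves with counting-like noise; hydrodynamic property
tables from WLC theory plus relative noise; and CD spectra as basis-sum
compositions plus an optional junctional term.  All are deterministic
given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._wlc import calibrated_kappa, chain_positions, sample_cos_bend
from .cd import BasisSet, SpectrumCD, _gaussian_sum, builtin_basis
from .flexibility import Environment, WLCParams, wlc_theory
from .io import CoordinateModel, PropertyRecord, ScatteringProfile
from .modeling import debye_intensity

__all__ = [
    "WLCChain",
    "JunctionSpec",
    "G4MultimerModel",
    "G4_UNIT_DIAMETER",
    "G4_UNIT_HEIGHT",
    "G4_STACK_GAP",
    "sample_wlc_chain",
    "build_g4_multimer",
    "simulate_saxs",
    "simulate_property_table",
    "simulate_cd",
]


# ---------------------------------------------------------------------------
# discrete worm-like chains
# ---------------------------------------------------------------------------

@dataclass
class WLCChain:
    positions: np.ndarray   # (n_seg + 1, 3), A
    l_seg: float
    lp: float
    seed: int

    @property
    def contour_length(self) -> float:
        return self.l_seg * (self.positions.shape[0] - 1)

    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


def sample_wlc_chain(L: float, lp: float, l_seg: float,
                     seed: int = 0, n_chains: int = 1):
    """Sample discrete WLC chain(s) of contour length ``L``.

    Bend angles follow p(theta) ~ exp(-(lp/l_seg)(1 - cos theta)) sin theta
    with uniform azimuths.  Returns a single WLCChain for ``n_chains == 1``,
    else a list.
    """
    if L < l_seg:
        raise ValueError("contour length below one segment")
    if lp <= 0:
        raise ValueError("persistence length must be positive")
    n_seg = max(int(round(L / l_seg)), 1)
    rng = np.random.default_rng(seed)
    if n_seg == 1:
        pos = np.zeros((n_chains, 2, 3))
        pos[:, 1, 2] = l_seg
    else:
        u_b = rng.random((n_chains, n_seg - 1))
        u_a = rng.random((n_chains, n_seg - 1))
        pos = chain_positions(n_seg, calibrated_kappa(lp / l_seg), u_b, u_a,
                              l_seg)
    chains = [WLCChain(positions=p, l_seg=l_seg, lp=lp, seed=seed)
              for p in pos]
    return chains[0] if n_chains == 1 else chains


# ---------------------------------------------------------------------------
# tandem G4 multimer bead models
# ---------------------------------------------------------------------------

# Unit geometry: a G4 unit is approximated as a 7-bead cluster filling a
# cylinder of the stated diameter and height; the stacking gap is calibrated
# once so that a 2-unit fully stacked model reproduces the measured
# dimer Rg of ~19.7 A, and then frozen.
G4_UNIT_DIAMETER = 24.0   # A
G4_UNIT_HEIGHT = 21.0     # A
G4_BEAD_RADIUS = 6.0      # A
G4_STACK_GAP = 16.0       # A (center-to-center spacing minus unit height)


@dataclass
class JunctionSpec:
    """Junction between consecutive G4 units.

    ``kind='stacked'`` places units coaxially in contact; ``kind='hinge'``
    bends the axis at the junction by an angle drawn from a von-Mises-like
    distribution of concentration ``kappa`` (or the fixed ``angle_deg`` if
    given) and releases the linker, adding ``extension`` A of unit
    separation (an unstacked junction is both bent and longer).
    """

    kind: str = "stacked"
    kappa: float = 4.0
    angle_deg: float | None = None
    # full release of the three-nucleotide TTA linker (~20 A of contour)
    extension: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("stacked", "hinge"):
            raise ValueError(f"unknown junction kind {self.kind!r}")


@dataclass
class G4MultimerModel:
    model: CoordinateModel
    topology_tags: list
    junctions: list
    unit_centers: np.ndarray


def _unit_beads() -> np.ndarray:
    """Bead offsets of one G4 unit (local frame, axis along z)."""
    r_ring = G4_UNIT_DIAMETER / 2.0 - G4_BEAD_RADIUS
    z_ax = G4_UNIT_HEIGHT / 2.0 - G4_BEAD_RADIUS
    beads = [(0.0, 0.0, 0.0), (0.0, 0.0, z_ax), (0.0, 0.0, -z_ax)]
    for k in range(4):
        ang = np.pi / 2.0 * k
        beads.append((r_ring * np.cos(ang), r_ring * np.sin(ang), 0.0))
    return np.array(beads)


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping +z onto ``axis`` (unit vector)."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, axis))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z, axis)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_g4_multimer(topology: str, junctions=None,
                      seed: int = 0) -> G4MultimerModel:
    """Tandem G4 bead model from a topology string (e.g. ``"212"``).

    Each character tags one unit's fold; units are identical 7-bead
    cylinder-like clusters.  ``junctions`` is one JunctionSpec per junction
    (default: all stacked).  Hinged junctions pivot at the inter-unit
    midpoint with a sampled (or fixed) bend angle; the model is
    reproducible given ``seed``.
    """
    tags = list(topology)
    if not tags:
        raise ValueError("empty topology string")
    if any(t not in "123" for t in tags):
        raise ValueError(f"unknown topology tag in {topology!r}")
    n_units = len(tags)
    if junctions is None:
        junctions = [JunctionSpec() for _ in range(n_units - 1)]
    if len(junctions) != n_units - 1:
        raise ValueError("need one junction spec per junction")
    rng = np.random.default_rng(seed)
    centers = [np.zeros(3)]
    axes = [np.array([0.0, 0.0, 1.0])]
    for j in junctions:
        sep = G4_UNIT_HEIGHT + G4_STACK_GAP
        t_old = axes[-1]
        if j.kind == "stacked":
            t_new = t_old
        else:
            sep += j.extension
            if j.angle_deg is not None:
                ct = float(np.cos(np.radians(j.angle_deg)))
            else:
                ct = float(sample_cos_bend(j.kappa, rng.random(1))[0])
            st = np.sqrt(max(1.0 - ct ** 2, 0.0))
            phi = 2.0 * np.pi * rng.random()
            R = _rotation_to(t_old)
            t_new = R @ np.array([st * np.cos(phi), st * np.sin(phi), ct])
        centers.append(centers[-1] + 0.5 * sep * t_old + 0.5 * sep * t_new)
        axes.append(t_new)
    beads = _unit_beads()
    xyz = []
    for c, ax in zip(centers, axes):
        xyz.append(beads @ _rotation_to(ax).T + c)
    xyz = np.vstack(xyz)
    n = xyz.shape[0]
    model = CoordinateModel(xyz, np.ones(n), np.full(n, G4_BEAD_RADIUS),
                            label=f"g4-{topology}", topology_tag=topology)
    return G4MultimerModel(model=model, topology_tags=tags,
                           junctions=list(junctions),
                           unit_centers=np.array(centers))


# ---------------------------------------------------------------------------
# noisy SAXS curves
# ---------------------------------------------------------------------------

def simulate_saxs(model: CoordinateModel, q_grid, i0_scale: float = 1.0,
                  noise_b: float = 0.01, noise_bg: float = 0.0,
                  seed: int = 0, label: str = "") -> ScatteringProfile:
    """Noisy SAXS profile of a bead model.

    The Debye curve is scaled to I(0) = ``i0_scale``; counting-like noise
    has sigma(q) = b * sqrt(I(q) + c_bg) and is added as N(0, sigma).
    ``noise_b = 0`` returns the exact theoretical curve with a small
    nominal sigma column.
    """
    q = np.asarray(q_grid, dtype=float)
    curve = debye_intensity(model, q)
    i0 = debye_intensity(model, np.array([1e-6])).i_model[0]
    i_th = curve.i_model * (i0_scale / i0)
    sigma = noise_b * np.sqrt(np.maximum(i_th + noise_bg, 0.0))
    rng = np.random.default_rng(seed)
    if noise_b > 0:
        i_noisy = i_th + rng.normal(0.0, sigma)
    else:
        i_noisy = i_th.copy()
        sigma = np.full_like(i_th, 1e-4 * i0_scale)
    return ScatteringProfile(q, i_noisy, sigma,
                             label=label or f"sim-{model.label}")


# ---------------------------------------------------------------------------
# noisy property tables
# ---------------------------------------------------------------------------

def simulate_property_table(true_params: WLCParams, construct_mws,
                            cv: float = 0.03, seed: int = 0,
                            env: Environment | None = None,
                            n_mc: int = 200) -> list[PropertyRecord]:
    """Per-construct (Rg, Dt, s20w) from WLC theory with relative noise.

    Each property is multiplied by (1 + N(0, cv)); per-property weights are
    proportional to 1/cv^2 (unit weights when cv = 0).
    """
    env = env or Environment()
    rng = np.random.default_rng(seed)
    w = 1.0 if cv == 0 else 1.0 / cv ** 2
    records = []
    for k, mw in enumerate(construct_mws):
        rg, dt, s = wlc_theory(mw, true_params, env, n_mc=n_mc)
        if cv > 0:
            rg, dt, s = (v * (1.0 + rng.normal(0.0, cv))
                         for v in (rg, dt, s))
        records.append(PropertyRecord(
            name=f"construct{k + 1}", mw=mw, rg=rg, dt=dt, s20w=s,
            weights={"rg": w, "dt": w, "s20w": w}))
    return records


# ---------------------------------------------------------------------------
# synthetic CD spectra
# ---------------------------------------------------------------------------

DEFAULT_JUNCTION_BANDS = [(240.0, 7.0, 40.0), (260.0, 8.0, -25.0),
                          (285.0, 8.0, -30.0)]


def junction_term(wavelength, bands=None) -> np.ndarray:
    """A junctional difference spectrum: positive band near 240 nm,
    negative bands near 260 and 285 nm."""
    wl = np.asarray(wavelength, dtype=float)
    return _gaussian_sum(wl, bands or DEFAULT_JUNCTION_BANDS)


def simulate_cd(compositions: dict, basis: BasisSet | None = None,
                junction_scale: float = 0.0, noise_sd: float = 0.0,
                seed: int = 0, junction_bands=None) -> dict:
    """Synthetic multimer spectra keyed by unit count N.

    ``compositions`` maps N -> multiset of basis names (length N).  Each
    spectrum is the basis sum, plus ``junction_scale`` times the junction
    term, plus additive Gaussian noise of SD ``noise_sd`` (Delta-eps units).
    """
    basis = basis or builtin_basis()
    rng = np.random.default_rng(seed)
    jt = junction_term(basis.wavelength, junction_bands)
    out = {}
    for n, multiset in sorted(compositions.items()):
        if len(tuple(multiset)) != n:
            raise ValueError(f"composition for N={n} must have {n} units")
        vals = sum(basis.spectra[k] for k in multiset) + junction_scale * jt
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, basis.wavelength.size)
        out[n] = SpectrumCD(basis.wavelength, vals, "deltaeps",
                            label=f"sim-N{n}")
    return out
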