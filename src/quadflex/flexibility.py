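"""Flexibility quantification of tandem G-quadruplex multimers.

Four connected analyses:

* **Swollen Gaussian coil fit** of Rg versus the number N of G4 units,
  Rg = lp * sqrt(N^(2v) / ((2v+1)(2v+2))), giving the persistence length
  lp and Flory exponent v.
* **Worm-like-chain property theory**: Rg by the Benoit-Doty closed form;
  Dt by Monte-Carlo-averaged Kirkwood friction over discrete WLC
  configurations of touching beads of hydrated diameter d; s by Svedberg.
* **Global WLC fit** (``hydfit_minimize``): minimize the mean-square
  relative deviation Delta^2 between calculated and experimental
  equivalent radii over (lp, ml, d), coarse grid then local refinement.
* **Bending-force model**: F = 1/2 kB T lp / R^2 for a chain of contour
  length L bent 180 degrees on a semicircular arc of radius R = L/pi.

Plus the SEC Stokes-radius calibration (log Rs vs Kd regression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._wlc import calibrated_kappa, chain_positions
from .io import PropertyRecord
from .modeling import A_TO_CM, KB, NA, SolventEnvironment, kirkwood_friction

__all__ = [
    "Environment",
    "FloryFit",
    "WLCParams",
    "EquivalentRadii",
    "rg_swollen",
    "fit_swollen",
    "wlc_theory",
    "equivalent_radii",
    "hydfit_minimize",
    "bending_force",
    "force_curve",
    "sec_calibration",
]

# Solvent/thermodynamic conditions; one type shared with the modeling layer.
Environment = SolventEnvironment

KB_SI = 1.380649e-23  # J/K


@dataclass
class FloryFit:
    lp: float
    v: float
    lp_err: float
    v_err: float
    r2: float
    covariance: np.ndarray
    at_bound: bool = False


@dataclass
class WLCParams:
    lp: float                  # persistence length, A
    ml: float                  # mass per unit length, Da/A
    d: float                   # hydrated chain diameter, A
    delta: float = float("nan")      # sqrt(Delta^2)
    pct_dev: float = float("nan")    # 100 * Delta
    on_boundary: bool = False
    profile: dict = field(default_factory=dict)


@dataclass
class EquivalentRadii:
    """Radii of the spheres sharing one measured property each (A)."""

    a_g: float | None = None   # from Rg
    a_t: float | None = None   # from Dt
    a_s: float | None = None   # from s20,w
    a_i: float | None = None   # from intrinsic viscosity (optional)

    def as_dict(self) -> dict:
        return {k: v for k, v in (("rg", self.a_g), ("dt", self.a_t),
                                  ("s20w", self.a_s), ("eta", self.a_i))
                if v is not None}


# ---------------------------------------------------------------------------
# swollen Gaussian coil
# ---------------------------------------------------------------------------

def rg_swollen(n, lp: float, v: float):
    """Rg of a swollen Gaussian coil of N statistical units.

    Rg = lp * sqrt(N^(2v) / ((2v+1)(2v+2))); v in [0.5, 1] spans ideal coil
    to rigid rod.
    """
    n = np.asarray(n, dtype=float)
    return lp * np.sqrt(n ** (2.0 * v) / ((2.0 * v + 1.0) * (2.0 * v + 2.0)))


def fit_swollen(n, rg, sigma_rg=None) -> FloryFit:
    """Weighted nonlinear least squares of (lp, v) to Rg(N) data.

    Requires >= 3 points over >= 3 distinct N.  v is constrained to
    [0.5, 1.0]; a solution pinned at a bound is flagged.
    """
    n = np.asarray(n, dtype=float)
    rg = np.asarray(rg, dtype=float)
    if n.size < 3 or np.unique(n).size < 3:
        raise ValueError("need >= 3 points spanning >= 3 distinct N")
    sigma = (np.asarray(sigma_rg, dtype=float)
             if sigma_rg is not None else np.full_like(rg, 1.0))
    try:
        popt, pcov = optimize.curve_fit(
            rg_swollen, n, rg, p0=[np.max(rg), 0.6], sigma=sigma,
            absolute_sigma=sigma_rg is not None,
            bounds=([1e-3, 0.5], [1e4, 1.0]), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"swollen-coil fit did not converge: {exc}") from exc
    lp, v = popt
    perr = np.sqrt(np.diag(pcov))
    resid = rg - rg_swollen(n, *popt)
    w = 1.0 / sigma ** 2
    ss_res = np.sum(w * resid ** 2)
    ss_tot = np.sum(w * (rg - np.average(rg, weights=w)) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    at_bound = bool(v < 0.5 + 1e-6 or v > 1.0 - 1e-6)
    if at_bound:
        warnings.warn("Flory exponent pinned at a bound", stacklevel=2)
    return FloryFit(lp=float(lp), v=float(v), lp_err=float(perr[0]),
                    v_err=float(perr[1]), r2=float(r2), covariance=pcov,
                    at_bound=at_bound)


# ---------------------------------------------------------------------------
# worm-like chain property theory
# ---------------------------------------------------------------------------

def rg_benoit_doty(L: float, lp: float) -> float:
    """Benoit-Doty Rg of an unperturbed worm-like chain (A).

    The stiff limit (L/lp small) uses the series Rg^2 = L^2/12 - L^3/(60 lp)
    + L^4/(360 lp^2) to avoid catastrophic cancellation of the closed form.
    """
    x = L / lp
    if x < 0.1:
        rg2 = L ** 2 / 12.0 - L ** 3 / (60.0 * lp) \
            + L ** 4 / (360.0 * lp ** 2)
    else:
        rg2 = (lp * L / 3.0 - lp ** 2 + 2.0 * lp ** 3 / L
               - (2.0 * lp ** 4 / L ** 2) * (1.0 - np.exp(-x)))
    return float(np.sqrt(rg2))


def wlc_theory(mw: float, params: WLCParams, env: Environment | None = None,
               n_mc: int = 200, seed: int = 20260101):
    """Theoretical (Rg, Dt, s20w) of a WLC of molecular weight ``mw`` Da.

    Contour length L = mw / ml.  Rg is the Benoit-Doty closed form.  Dt is
    the Monte-Carlo average of the Kirkwood double-sum friction over
    discrete-WLC configurations of touching beads of diameter d (the chain
    is divided into round(L/d) segments with a bead at each segment
    midpoint).  s follows from the Svedberg relation
    s = mw (1 - vbar rho) Dt / (NA kB T).

    The sampler uses a fixed seed so the theory is a deterministic, smooth
    function of the parameters (common random numbers).
    """
    env = env or Environment()
    L = mw / params.ml
    if L <= 0:
        raise ValueError("non-positive contour length")
    if L < params.d:
        raise ValueError(f"contour length {L:.1f} A below one bead "
                         f"diameter {params.d:.1f} A")
    rg = rg_benoit_doty(L, params.lp)
    n_seg = max(int(round(L / params.d)), 2)
    l_seg = L / n_seg
    rng = np.random.default_rng(seed)
    u_b = rng.random((n_mc, n_seg - 1))
    u_a = rng.random((n_mc, n_seg - 1))
    pos = chain_positions(n_seg, calibrated_kappa(params.lp / l_seg),
                          u_b, u_a, l_seg)
    mids = 0.5 * (pos[:, 1:, :] + pos[:, :-1, :]) * A_TO_CM
    a_cm = 0.5 * params.d * A_TO_CM
    # batched Kirkwood double-sum over all chains
    diff = mids[:, :, None, :] - mids[:, None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    iu = np.triu_indices(n_seg, 1)
    inv_sum = 2.0 * np.sum(1.0 / np.maximum(dist[:, iu[0], iu[1]],
                                            1e-3 * a_cm), axis=1)
    f1 = 6.0 * np.pi * env.eta * a_cm
    f = n_seg * f1 / (1.0 + (f1 / (6.0 * np.pi * env.eta * n_seg)) * inv_sum)
    dt = float(np.mean(KB * env.T / f))
    s = mw * (1.0 - env.vbar * env.rho) * dt / (NA * KB * env.T) / 1e-13
    return rg, dt, float(s)


# ---------------------------------------------------------------------------
# equivalent radii
# ---------------------------------------------------------------------------

def equivalent_radii(record: PropertyRecord,
                     env: Environment | None = None) -> EquivalentRadii:
    """Radii of equivalent spheres from each measured property.

    a_G = sqrt(5/3) Rg; a_T = kB T / (6 pi eta Dt); a_S from the Stokes
    sphere with the record's friction f = M (1 - vbar rho) / (NA s).
    """
    env = env or Environment()
    out = EquivalentRadii()
    if record.rg is not None:
        out.a_g = float(np.sqrt(5.0 / 3.0) * record.rg)
    if record.dt is not None:
        out.a_t = float(KB * env.T / (6.0 * np.pi * env.eta * record.dt)
                        / A_TO_CM)
    if record.s20w is not None:
        f = record.mw * (1.0 - env.vbar * env.rho) / (NA * record.s20w * 1e-13)
        out.a_s = float(f / (6.0 * np.pi * env.eta) / A_TO_CM)
    return out


def _calc_radii(mw: float, params: WLCParams, env: Environment,
                n_mc: int, seed: int) -> dict:
    rg, dt, s = wlc_theory(mw, params, env, n_mc=n_mc, seed=seed)
    rec = PropertyRecord(name="calc", mw=mw, rg=rg, dt=dt, s20w=s)
    return equivalent_radii(rec, env).as_dict()


# ---------------------------------------------------------------------------
# global WLC fit
# ---------------------------------------------------------------------------

DEFAULT_RANGES = {"lp": (20.0, 100.0), "ml": (10.0, 300.0),
                  "d": (10.0, 100.0)}


def _delta2(table, exp_radii, p, env, n_mc, seed, ranges):
    lp, ml, d = p
    for val, (lo, hi) in zip((lp, ml, d),
                             (ranges["lp"], ranges["ml"], ranges["d"])):
        if not lo <= val <= hi:
            return 1e6
    params = WLCParams(lp=lp, ml=ml, d=d)
    total = 0.0
    for rec, exp_r in zip(table, exp_radii):
        try:
            cal = _calc_radii(rec.mw, params, env, n_mc, seed)
        except ValueError:
            return 1e6
        wsum = 0.0
        acc = 0.0
        for prop, a_exp in exp_r.items():
            w = rec.weights.get(prop, 1.0)
            acc += w * ((cal[prop] - a_exp) / a_exp) ** 2
            wsum += w
        total += acc / wsum
    return total / len(table)


def hydfit_minimize(table: list[PropertyRecord],
                    ranges: dict | None = None,
                    env: Environment | None = None,
                    n_mc: int = 200, seed: int = 20260101,
                    grid_shape=(9, 14, 7)) -> WLCParams:
    """Global WLC fit of a multi-construct property table.

    Minimizes Delta^2(lp, ml, d) = (1/Ns) sum_samples [ (sum_Y w_Y)^-1 *
    sum_Y w_Y ((a_Y(cal) - a_Y(exp)) / a_Y(exp))^2 ] by a coarse grid over
    the search ranges followed by Nelder-Mead refinement.  Reports 100*Delta
    and one-at-a-time sensitivity profiles; solutions on a range boundary
    are flagged.
    """
    if len(table) < 2:
        raise ValueError("need >= 2 constructs")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    env = env or Environment()
    exp_radii = [equivalent_radii(rec, env).as_dict() for rec in table]
    if all(sum(rec.weights.values()) == 0 for rec in table):
        raise ValueError("all property weights are zero")

    def fun(p):
        return _delta2(table, exp_radii, p, env, n_mc, seed, ranges)

    best_val, best_p = np.inf, None
    lps = np.linspace(*ranges["lp"], grid_shape[0])
    mls = np.linspace(max(ranges["ml"][0], 40.0), ranges["ml"][1],
                      grid_shape[1])
    ds = np.linspace(*ranges["d"], grid_shape[2])
    for lp in lps:
        for ml in mls:
            for d in ds:
                v = fun((lp, ml, d))
                if v < best_val:
                    best_val, best_p = v, (lp, ml, d)
    res = optimize.minimize(fun, best_p, method="Nelder-Mead",
                            options={"xatol": 0.05, "fatol": 1e-12,
                                     "maxiter": 2000})
    lp, ml, d = res.x
    delta2 = float(res.fun)
    on_boundary = any(
        abs(val - lo) < 1e-6 * (hi - lo) or abs(val - hi) < 1e-6 * (hi - lo)
        for val, (lo, hi) in zip(res.x, (ranges["lp"], ranges["ml"],
                                         ranges["d"])))
    if on_boundary:
        warnings.warn("WLC fit minimum lies on a search-range boundary",
                      stacklevel=2)
    # one-at-a-time sensitivity profiles around the optimum
    profile = {}
    for name, val, (lo, hi) in (("lp", lp, ranges["lp"]),
                                ("ml", ml, ranges["ml"]),
                                ("d", d, ranges["d"])):
        grid = np.linspace(max(lo, 0.8 * val), min(hi, 1.2 * val), 9)
        vals = []
        for g in grid:
            p = {"lp": lp, "ml": ml, "d": d}
            p[name] = g
            vals.append(fun((p["lp"], p["ml"], p["d"])))
        profile[name] = (grid, np.array(vals))
    return WLCParams(lp=float(lp), ml=float(ml), d=float(d),
                     delta=float(np.sqrt(delta2)),
                     pct_dev=float(100.0 * np.sqrt(delta2)),
                     on_boundary=on_boundary, profile=profile)


# ---------------------------------------------------------------------------
# bending force
# ---------------------------------------------------------------------------

def bending_force(lp: float, contour_length: float, T: float = 293.15,
                  geometry: str = "contour") -> float:
    """Force (pN) to hold a chain bent 180 degrees on a semicircular arc.

    F = 1/2 kB T lp / R^2.  In the default ``contour`` geometry the chain of
    contour length L lies along the arc, so R = L / pi; in ``end-to-end``
    geometry ``contour_length`` is read as the end-to-end span 2R.
    """
    if lp <= 0 or contour_length <= 0:
        raise ValueError("lengths must be positive")
    if geometry == "contour":
        R = contour_length / np.pi
    elif geometry == "end-to-end":
        R = contour_length / 2.0
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    R_m = R * 1e-10
    lp_m = lp * 1e-10
    return float(0.5 * KB_SI * T * lp_m / R_m ** 2 * 1e12)


def force_curve(lp: float, length_grid, T: float = 293.15,
                geometry: str = "contour") -> np.ndarray:
    """Vectorized bending_force over a grid of lengths; returns (L, F) rows."""
    lengths = np.asarray(length_grid, dtype=float)
    forces = np.array([bending_force(lp, L, T, geometry) for L in lengths])
    return np.column_stack([lengths, forces])


# ---------------------------------------------------------------------------
# SEC Stokes-radius calibration
# ---------------------------------------------------------------------------

def sec_calibration(kd_standards, rs_standards, kd_sample,
                    env: Environment | None = None) -> dict:
    """Stokes radius of a sample from a log(Rs)-vs-Kd standard regression.

    Returns the regression (slope, intercept, r2), the predicted Rs (A) with
    a 95% prediction interval, and the Stokes-Einstein Dt (cm^2/s).  An
    extrapolation outside the standards' Kd range is flagged with a warning.
    """
    kd = np.asarray(kd_standards, dtype=float)
    rs = np.asarray(rs_standards, dtype=float)
    if kd.size < 3:
        raise ValueError("need >= 3 standards")
    env = env or Environment()
    res = stats.linregress(kd, np.log10(rs))
    if not (kd.min() <= kd_sample <= kd.max()):
        warnings.warn("sample Kd outside the standards' range "
                      "(extrapolation)", stacklevel=2)
    log_rs = res.slope * kd_sample + res.intercept
    rs_pred = 10.0 ** log_rs
    # 95% prediction interval on log10(Rs)
    n = kd.size
    resid = np.log10(rs) - (res.slope * kd + res.intercept)
    s_err = np.sqrt(np.sum(resid ** 2) / max(n - 2, 1))
    sx2 = np.sum((kd - kd.mean()) ** 2)
    se_pred = s_err * np.sqrt(1.0 + 1.0 / n + (kd_sample - kd.mean()) ** 2
                              / sx2)
    tval = stats.t.ppf(0.975, max(n - 2, 1))
    interval = (10.0 ** (log_rs - tval * se_pred),
                10.0 ** (log_rs + tval * se_pred))
    dt = KB * env.T / (6.0 * np.pi * env.eta * rs_pred * A_TO_CM)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "rs": float(rs_pred),
            "rs_interval": interval, "dt": float(dt)}
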