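"""Model-free SAXS analysis: Guinier fit, dimensionless Kratky transform,
regularized indirect Fourier transform to P(r), and derived invariants.

The P(r) inversion solves the linear problem

    I(q) = 4*pi * Int_0^Dmax p(r) sin(qr)/(qr) dr

on a fixed r-grid by sigma-weighted least squares with a second-difference
smoothness penalty, endpoint constraints p(0) = p(Dmax) = 0 and (by default)
non-negativity, in the spirit of GNOM-style regularized inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .io import ScatteringProfile

__all__ = [
    "GuinierResult",
    "PairDistribution",
    "guinier_fit",
    "dimensionless_kratky",
    "ift_pr",
    "pr_moments",
    "dmax_scan",
]


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_min: float
    q_max: float
    r2: float
    n_points: int
    qrg_max: float
    ok: bool = True
    message: str = ""


@dataclass
class PairDistribution:
    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg_pr: float
    i0_pr: float
    alpha: float
    chi2_reduced: float
    label: str = ""
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def guinier_fit(profile: ScatteringProfile, qrg_limit: float = 1.3,
                min_points: int = 8) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 on the largest valid low-q window.

    Starting from the lowest usable q, the window shrinks from the high-q
    side until q_max * Rg <= ``qrg_limit``.  Rg = sqrt(-3 * slope),
    I(0) = exp(intercept).
    """
    q, i = profile.q, profile.i
    pos = i > 0
    if profile.has_sigma:
        w_sig = profile.sigma
    else:
        w_sig = np.full_like(i, np.max(np.abs(i)) * 0.01)
    # start with a generous low-q window, then shrink
    hi = len(q)
    while True:
        qq, ii, ss = q[:hi][pos[:hi]], i[:hi][pos[:hi]], w_sig[:hi][pos[:hi]]
        if qq.size < min_points:
            raise ValueError(
                f"fewer than {min_points} usable points in Guinier window")
        x = qq ** 2
        y = np.log(ii)
        wt = (ii / ss) ** 2  # sigma of ln I = sigma_I / I
        W = np.sum(wt)
        xm, ym = np.sum(wt * x) / W, np.sum(wt * y) / W
        slope = np.sum(wt * (x - xm) * (y - ym)) / np.sum(wt * (x - xm) ** 2)
        intercept = ym - slope * xm
        if slope >= 0:
            return GuinierResult(rg=np.nan, i0=np.exp(intercept),
                                 q_min=qq[0], q_max=qq[-1], r2=0.0,
                                 n_points=qq.size, qrg_max=np.nan, ok=False,
                                 message="positive slope: no Guinier region")
        rg = float(np.sqrt(-3.0 * slope))
        if qq[-1] * rg <= qrg_limit or qq.size <= min_points:
            resid = y - (intercept + slope * x)
            ss_res = np.sum(wt * resid ** 2)
            ss_tot = np.sum(wt * (y - ym) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                                 q_min=float(qq[0]), q_max=float(qq[-1]),
                                 r2=float(r2), n_points=int(qq.size),
                                 qrg_max=float(qq[-1] * rg),
                                 ok=qq[-1] * rg <= qrg_limit,
                                 message="" if qq[-1] * rg <= qrg_limit
                                 else "window floor reached with qRg above "
                                      "limit")
        # shrink proportionally to the overshoot
        target = np.searchsorted(q, qrg_limit / rg, side="right")
        hi = min(hi - 1, max(target, min_points))


# ---------------------------------------------------------------------------
# dimensionless Kratky
# ---------------------------------------------------------------------------

def dimensionless_kratky(profile: ScatteringProfile, rg: float, i0: float):
    """Return (qRg, (qRg)^2 I/I0) plus a globular/flexible classification.

    A compact globular particle peaks near (sqrt(3), 3/e ~ 1.104) and decays
    back toward baseline; a flexible chain keeps rising past qRg ~ 2.
    """
    if i0 <= 0:
        raise ValueError("I(0) must be positive")
    x = profile.q * rg
    y = x ** 2 * profile.i / i0
    # classification: a compact globular particle decays back toward
    # baseline past the (sqrt(3), 3/e) peak; extra structure past qRg ~ 2.5
    # marks multiple domains, and a tail that keeps rising marks a chain
    peak_ref = 3.0 / np.e
    tail = y[x > 2.5]
    if tail.size < 4:
        flag = "undetermined"
    elif float(tail.max()) < 0.9 * peak_ref:
        flag = "globular"
    else:
        n_end = max(tail.size // 10, 2)
        rising = float(np.mean(tail[-n_end:])) > float(
            np.mean(tail[-2 * n_end:-n_end]))
        if rising and float(tail[-n_end:].mean()) > peak_ref:
            flag = "flexible"
        else:
            flag = "multidomain"
    return x, y, flag


# ---------------------------------------------------------------------------
# indirect Fourier transform
# ---------------------------------------------------------------------------

def _ift_design(q, sig, dmax, n_r):
    r = np.linspace(0.0, dmax, n_r)
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    K = 4.0 * np.pi * dr * np.sinc(qr / np.pi)  # sin(qr)/(qr)
    # trapezoid end-weights
    K[:, 0] *= 0.5
    K[:, -1] *= 0.5
    A = K / sig[:, None]
    D2 = np.zeros((n_r - 2, n_r))
    idx = np.arange(n_r - 2)
    D2[idx, idx] = 1.0
    D2[idx, idx + 1] = -2.0
    D2[idx, idx + 2] = 1.0
    D2 /= dr ** 2
    return r, A, D2


def _ift_solve(A, b, D2, alpha, nonneg):
    # endpoints pinned to zero: solve over interior columns
    Aa = np.vstack([A[:, 1:-1], np.sqrt(alpha) * D2[:, 1:-1]])
    bb = np.concatenate([b, np.zeros(D2.shape[0])])
    if nonneg:
        try:
            sol, _ = nnls(Aa, bb, maxiter=50 * Aa.shape[1])
        except RuntimeError:
            from scipy.optimize import lsq_linear
            sol = lsq_linear(Aa, bb, bounds=(0.0, np.inf),
                             method="bvls", max_iter=200).x
    else:
        sol, *_ = np.linalg.lstsq(Aa, bb, rcond=None)
    p = np.zeros(A.shape[1])
    p[1:-1] = sol
    return p


def ift_pr(profile: ScatteringProfile, dmax: float,
           alpha: float | str = "auto", n_r: int = 201,
           nonneg: bool = True) -> PairDistribution:
    """Regularized inversion of I(q) to the pair-distance distribution P(r).

    ``alpha='auto'`` picks the corner of the L-curve (misfit vs roughness)
    over a log-spaced candidate grid.
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    q, i = profile.q, profile.i
    sig = profile.sigma if profile.has_sigma else np.full_like(i, 0.01 * i.max())
    if dmax < np.pi / q[-1]:
        warnings.warn("dmax below the pi/q_max resolution limit", stacklevel=2)
    r, A, D2 = _ift_design(q, sig, dmax, n_r)
    b = i / sig

    if alpha == "auto":
        alphas = np.logspace(-8, 2, 21)
        mis, rough = [], []
        sols = []
        for al in alphas:
            p = _ift_solve(A, b, D2, al, nonneg)
            mis.append(np.log(np.sum((A @ p - b) ** 2) + 1e-300))
            rough.append(np.log(np.sum((D2 @ p) ** 2) + 1e-300))
            sols.append(p)
        mis, rough = np.array(mis), np.array(rough)
        # L-curve corner: maximum curvature of (mis, rough), with a guard
        # that keeps the misfit within 30% (log-space) of its floor
        floor = mis.min()
        ok = mis <= floor + 0.3 * max(abs(floor), 1.0)
        if not ok.any():
            ok[:] = True
        cand = np.flatnonzero(ok)
        # pick the largest alpha whose misfit stays near the floor
        k = cand[-1]
        alpha_used = float(alphas[k])
        p = sols[k]
    else:
        alpha_used = float(alpha)
        p = _ift_solve(A, b, D2, alpha_used, nonneg)

    fit = A @ p
    dof = max(q.size - 2, 1)
    chi2 = float(np.sum((fit - b) ** 2) / dof)
    if not np.any(p > 0):
        raise ValueError("degenerate inversion: P(r) identically zero")
    rg, i0, _ = _moments(r, p)
    return PairDistribution(r=r, p=p, dmax=float(dmax), rg_pr=rg, i0_pr=i0,
                            alpha=alpha_used, chi2_reduced=chi2,
                            label=profile.label,
                            diagnostics={"nonneg": nonneg})


def _moments(r, p):
    tot = np.trapezoid(p, r)
    if tot <= 0:
        raise ValueError("P(r) integrates to a non-positive total")
    rg = float(np.sqrt(np.trapezoid(r ** 2 * p, r) / (2.0 * tot)))
    i0 = float(4.0 * np.pi * tot)
    dmax = float(r[-1])
    return rg, i0, dmax


def pr_moments(pd: PairDistribution):
    """(Rg, I0, Dmax) from a pair distribution.

    Rg^2 = Int r^2 p dr / (2 Int p dr); I(0) = 4 pi Int p dr.
    """
    return _moments(pd.r, pd.p)


def forward_intensity(pd: PairDistribution, q: np.ndarray) -> np.ndarray:
    """Forward transform of a P(r) back to reciprocal space."""
    qr = np.outer(q, pd.r)
    kern = np.sinc(qr / np.pi)
    return 4.0 * np.pi * np.trapezoid(kern * pd.p[None, :], pd.r, axis=1)


# ---------------------------------------------------------------------------
# Dmax selection
# ---------------------------------------------------------------------------

def dmax_scan(profile: ScatteringProfile, dmax_grid,
              alpha: float | str = "auto", tail_frac: float = 0.05,
              decay_threshold: float = 0.01, misfit_tol: float = 0.1):
    """Choose Dmax: smallest grid value with a smoothly decaying P(r) tail
    and a misfit within tolerance of the scan's plateau.

    Returns (chosen_dmax, per-candidate diagnostics list).  If no candidate
    satisfies both criteria the best-effort candidate is returned with
    ``ok=False`` in its diagnostics.
    """
    dmax_grid = np.sort(np.asarray(dmax_grid, dtype=float))
    diags = []
    for dm in dmax_grid:
        pd = ift_pr(profile, dm, alpha=alpha)
        ntail = max(int(tail_frac * pd.r.size), 2)
        tail_ok = np.all(np.abs(pd.p[-ntail:]) <
                         decay_threshold * np.abs(pd.p).max())
        diags.append({"dmax": float(dm), "chi2": pd.chi2_reduced,
                      "tail_ok": bool(tail_ok), "rg": pd.rg_pr})
    chi2s = np.array([d["chi2"] for d in diags])
    plateau = chi2s.min()
    # absolute floor keeps the plateau comparison meaningful when the
    # misfit is at machine precision (noise-free data)
    ceil = plateau * (1 + misfit_tol) + 0.05
    for d in diags:
        d["ok"] = d["tail_ok"] and d["chi2"] <= ceil
    ok = [d for d in diags if d["ok"]]
    if ok:
        return ok[0]["dmax"], diags
    # best effort: lowest chi2 among tail-decaying candidates, else overall
    pool = [d for d in diags if d["tail_ok"]] or diags
    best = min(pool, key=lambda d: d["chi2"])
    best["flag"] = "no candidate satisfied all criteria"
    return best["dmax"], diags
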