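"""Low-level discrete worm-like-chain sampling shared by the flexibility
theory and the synthetic-data generators.

A discrete WLC of segment length l_seg and persistence length lp has bend
angles theta between successive tangents distributed as

    p(theta) d(theta)  proportional to  exp(kappa * cos(theta)) sin(theta),
    kappa = lp / l_seg,

which admits the closed-form inverse CDF
cos(theta) = 1 + ln(u + (1 - u) e^{-2 kappa}) / kappa for u ~ U(0, 1).
Azimuths are uniform.  Sampling with a fixed uniform-draw array gives
common random numbers across parameter values (smooth objectives).
"""

from __future__ import annotations

import numpy as np


def langevin(kappa: float) -> float:
    """<cos theta> of the density exp(kappa cos) sin: coth(kappa) - 1/kappa."""
    if kappa < 1e-6:
        return kappa / 3.0
    if kappa > 30.0:
        return 1.0 - 1.0 / kappa
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def calibrated_kappa(lp_over_lseg: float) -> float:
    """Stiffness kappa for which the sampled chain's tangent correlation is
    exactly exp(-l_seg/lp).

    The exponential density gives <cos theta> = coth(kappa) - 1/kappa, which
    equals the nominal exp(-1/delta) only in the stiff limit; solving for
    kappa makes the realized persistence length match the requested one at
    any discretization.
    """
    from scipy.optimize import brentq

    if lp_over_lseg > 1e5:  # effectively rigid
        return float(lp_over_lseg)
    target = np.exp(-1.0 / lp_over_lseg)
    if target <= langevin(1e-6):
        return 1e-6
    return brentq(lambda k: langevin(k) - target, 1e-6, 1e6, xtol=1e-10)


def sample_cos_bend(kappa: float, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF sample of cos(theta) for stiffness kappa = lp/l_seg."""
    if kappa < 1e-9:
        return 1.0 - 2.0 * u  # freely jointed limit
    with np.errstate(over="ignore", divide="ignore"):
        e = np.exp(-2.0 * kappa)
        c = 1.0 + np.log(u + (1.0 - u) * e) / kappa
    return np.clip(c, -1.0, 1.0)


def chain_positions(n_seg: int, kappa: float, u_bend: np.ndarray,
                    u_azi: np.ndarray, l_seg: float = 1.0) -> np.ndarray:
    """Vertex positions of discrete WLC chains.

    ``u_bend``/``u_azi`` have shape (n_chains, n_seg - 1); the returned
    array is (n_chains, n_seg + 1, 3) in units of ``l_seg``.
    """
    n_chains = u_bend.shape[0]
    cos_t = sample_cos_bend(kappa, u_bend)
    phi = 2.0 * np.pi * u_azi
    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0
    pos = np.zeros((n_chains, n_seg + 1, 3))
    for j in range(n_seg):
        pos[:, j + 1] = pos[:, j] + t
        if j < n_seg - 1:
            ct = cos_t[:, j]
            st = np.sqrt(np.clip(1.0 - ct ** 2, 0.0, None))
            ref = np.where(np.abs(t[:, 2:3]) < 0.9,
                           np.array([0.0, 0.0, 1.0]),
                           np.array([1.0, 0.0, 0.0]))
            e1 = np.cross(t, ref)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            t = (ct[:, None] * t
                 + st[:, None] * (np.cos(phi[:, j])[:, None] * e1
                                  + np.sin(phi[:, j])[:, None] * e2))
    return pos * l_seg
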