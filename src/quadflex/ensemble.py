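"""Ensemble optimization: select a weighted sub-ensemble of theoretical
curves that fits an experimental profile.

A genetic algorithm evolves fixed-length multisets of pool-member indices
(null genes realize ensembles smaller than the maximum size).  Candidate
fitness is the reduced discrepancy

    chi^2 = 1/(K-1) * sum_j [ (mu * I_ens(s_j) - I_exp(s_j)) / sigma(s_j) ]^2

with the scale mu (and, optionally, a bounded constant offset) solved in
closed form per candidate.  The GA is restarted ``repeats`` times and the
best solution across repeats is returned together with the per-repeat
chi^2 distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CoordinateModel, ScatteringProfile
from .modeling import SolventEnvironment, debye_intensity, kirkwood_hydro

__all__ = [
    "CurvePool",
    "GAConfig",
    "EnsembleSolution",
    "build_pool",
    "gajoe_select",
    "ensemble_stats",
]


@dataclass
class CurvePool:
    q: np.ndarray
    curves: np.ndarray            # (K, nq)
    labels: list
    topology_tags: list
    rg_model: np.ndarray
    dmax_model: np.ndarray
    s20w_model: np.ndarray

    @property
    def size(self) -> int:
        return self.curves.shape[0]


@dataclass
class GAConfig:
    max_ensemble: int = 30
    min_ensemble: int = 1
    allow_repetition: bool = True
    constant_subtraction: bool = True
    repeats: int = 200
    population: int = 50
    generations: int = 1000
    stagnation: int = 100
    mutation_rate: float = 0.1
    crossover_rate: float = 0.5
    elite_fraction: float = 0.1
    seed: int = 0


@dataclass
class EnsembleSolution:
    indices: np.ndarray            # selected member indices (with repeats)
    weights: dict                  # member index -> weight (sums to 1)
    chi2: float
    scale: float
    offset: float
    flexibility: float | None = None
    repeat_chi2: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------

def build_pool(models: list[CoordinateModel], q_grid,
               env: SolventEnvironment | None = None,
               mws: list[float] | None = None) -> CurvePool:
    """Debye curves plus per-model Rg/Dmax/s20w metadata.

    Duplicate models are kept as-is: repetition semantics of the selector
    require that identical members stay distinguishable by index.
    """
    if len(models) < 2:
        raise ValueError("pool requires at least 2 models")
    env = env or SolventEnvironment()
    q = np.asarray(q_grid, dtype=float)
    curves, rg, dmax, s20 = [], [], [], []
    for k, m in enumerate(models):
        curves.append(debye_intensity(m, q).i_model)
        rg.append(m.rg())
        dmax.append(m.dmax())
        mw = mws[k] if mws is not None else None
        s20.append(kirkwood_hydro(m, env, mw=mw).s20w)
    return CurvePool(q=q, curves=np.array(curves),
                     labels=[m.label for m in models],
                     topology_tags=[m.topology_tag for m in models],
                     rg_model=np.array(rg), dmax_model=np.array(dmax),
                     s20w_model=np.array(s20))


# ---------------------------------------------------------------------------
# chi^2 of a candidate ensemble
# ---------------------------------------------------------------------------

def _chi2_closed_form(i_ens, i_exp, sig, allow_offset, offset_bound):
    """Scale (and bounded offset) in closed form; returns (chi2, mu, c)."""
    w = 1.0 / sig ** 2
    K = i_exp.size
    if allow_offset:
        # minimize sum w (mu*I + c - I_exp)^2 over (mu, c)
        swx2 = np.sum(w * i_ens ** 2)
        swx = np.sum(w * i_ens)
        sw = np.sum(w)
        swxy = np.sum(w * i_ens * i_exp)
        swy = np.sum(w * i_exp)
        det = swx2 * sw - swx ** 2
        if det > 0:
            mu = (swxy * sw - swx * swy) / det
            c = (swx2 * swy - swx * swxy) / det
        else:
            mu, c = swxy / swx2, 0.0
        if abs(c) > offset_bound:
            c = np.sign(c) * offset_bound
            mu = (swxy - c * swx) / swx2
    else:
        mu = np.sum(w * i_ens * i_exp) / np.sum(w * i_ens ** 2)
        c = 0.0
    resid = (mu * i_ens + c - i_exp) / sig
    return float(np.sum(resid ** 2) / (K - 1)), float(mu), float(c)


def _evaluate(genes, pool_curves, i_exp, sig, allow_offset, offset_bound):
    active = genes[genes >= 0]
    if active.size == 0:
        return np.inf, 1.0, 0.0
    i_ens = pool_curves[active].mean(axis=0)
    return _chi2_closed_form(i_ens, i_exp, sig, allow_offset, offset_bound)


def _evaluate_population(pop, pool_curves, i_exp, sig, allow_offset,
                         offset_bound):
    """Vectorized chi^2 of a list of chromosomes (scale/offset closed form)."""
    K_pool = pool_curves.shape[0]
    counts = np.zeros((len(pop), K_pool))
    for r, genes in enumerate(pop):
        active = genes[genes >= 0]
        if active.size:
            np.add.at(counts[r], active, 1.0 / active.size)
    i_ens = counts @ pool_curves          # (pop, nq)
    w = 1.0 / sig ** 2
    K = i_exp.size
    swx2 = i_ens ** 2 @ w
    swxy = i_ens @ (w * i_exp)
    empty = swx2 <= 0
    swx2[empty] = 1.0
    if allow_offset:
        swx = i_ens @ w
        sw = float(np.sum(w))
        swy = float(np.sum(w * i_exp))
        det = swx2 * sw - swx ** 2
        safe = det > 1e-300
        mu = np.where(safe, (swxy * sw - swx * swy) / np.where(safe, det, 1),
                      swxy / swx2)
        c = np.where(safe, (swx2 * swy - swx * swxy) / np.where(safe, det, 1),
                     0.0)
        clip = np.abs(c) > offset_bound
        c = np.where(clip, np.sign(c) * offset_bound, c)
        mu = np.where(clip, (swxy - c * swx) / swx2, mu)
    else:
        mu = swxy / swx2
        c = np.zeros_like(mu)
    resid = (mu[:, None] * i_ens + c[:, None] - i_exp[None, :]) / sig[None, :]
    chi2 = np.sum(resid ** 2, axis=1) / (K - 1)
    chi2[empty] = np.inf
    return chi2


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _random_chromosome(rng, K, cfg):
    n_active = rng.integers(cfg.min_ensemble, cfg.max_ensemble + 1)
    genes = np.full(cfg.max_ensemble, -1, dtype=int)
    if cfg.allow_repetition:
        genes[:n_active] = rng.integers(0, K, n_active)
    else:
        genes[:n_active] = rng.choice(K, size=min(n_active, K), replace=False)
    return genes


def _repair(genes, rng, K, cfg):
    """Enforce ensemble-size bounds and (optionally) uniqueness."""
    if not cfg.allow_repetition:
        seen = set()
        for i, g in enumerate(genes):
            if g >= 0 and g in seen:
                genes[i] = -1
            elif g >= 0:
                seen.add(g)
    n_active = int(np.sum(genes >= 0))
    while n_active < cfg.min_ensemble:
        slot = rng.integers(0, genes.size)
        if genes[slot] < 0:
            g = rng.integers(0, K)
            if cfg.allow_repetition or g not in genes:
                genes[slot] = g
                n_active += 1
    return genes


def _ga_once(pool_curves, i_exp, sig, cfg, rng, offset_bound):
    K = pool_curves.shape[0]
    pop = [_random_chromosome(rng, K, cfg) for _ in range(cfg.population)]
    n_elite = max(1, int(cfg.elite_fraction * cfg.population))
    best_genes, best_fit = None, np.inf
    stagnant = 0
    for _gen in range(cfg.generations):
        fits = _evaluate_population(pop, pool_curves, i_exp, sig,
                                    cfg.constant_subtraction, offset_bound)
        order = np.argsort(fits)
        if fits[order[0]] < best_fit - 1e-12:
            best_fit = fits[order[0]]
            best_genes = pop[order[0]].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= cfg.stagnation:
                break
        elite = [pop[i].copy() for i in order[:n_elite]]
        # rank-based selection among the top half
        parents_pool = [pop[i] for i in order[:max(2, cfg.population // 2)]]
        children = []
        while len(children) < cfg.population - n_elite:
            pa, pb = rng.choice(len(parents_pool), 2, replace=True)
            a = parents_pool[pa].copy()
            b = parents_pool[pb]
            if rng.random() < cfg.crossover_rate:
                cut = rng.integers(1, a.size)
                a[cut:] = b[cut:]
            # per-gene mutation: new random index or null
            mask = rng.random(a.size) < cfg.mutation_rate
            if mask.any():
                a[mask] = rng.integers(-1, K, int(mask.sum()))
            children.append(_repair(a, rng, K, cfg))
        pop = elite + children
    return best_genes, best_fit


def gajoe_select(pool: CurvePool, profile: ScatteringProfile,
                 cfg: GAConfig | None = None) -> EnsembleSolution:
    """GA search for the minimal-chi^2 weighted sub-ensemble.

    Deterministic given ``cfg.seed``.  The best solution across
    ``cfg.repeats`` independent GA runs is returned; ``repeat_chi2`` holds
    each run's best chi^2.
    """
    cfg = cfg or GAConfig()
    if pool.size == 0:
        raise ValueError("empty pool")
    q = profile.q
    if q.size != pool.q.size or not np.allclose(q, pool.q):
        raise ValueError("profile and pool q-grids differ; resample first")
    if not profile.has_sigma:
        raise ValueError("ensemble selection requires sigma")
    sig = profile.sigma
    if np.any(sig <= 0) or not np.all(np.isfinite(sig)):
        raise ValueError("degenerate sigma")
    offset_bound = (0.05 * float(np.max(profile.i))
                    if cfg.constant_subtraction else 0.0)
    master = np.random.default_rng(cfg.seed)
    best_genes, best_fit = None, np.inf
    repeat_chi2 = []
    for _rep in range(cfg.repeats):
        rng = np.random.default_rng(master.integers(2 ** 31))
        genes, fit = _ga_once(pool.curves, profile.i, sig, cfg, rng,
                              offset_bound)
        repeat_chi2.append(fit)
        if fit < best_fit:
            best_fit, best_genes = fit, genes
    chi2, mu, c = _evaluate(best_genes, pool.curves, profile.i, sig,
                            cfg.constant_subtraction, offset_bound)
    active = np.sort(best_genes[best_genes >= 0])
    uniq, counts = np.unique(active, return_counts=True)
    weights = {int(k): float(n) / active.size for k, n in zip(uniq, counts)}
    return EnsembleSolution(indices=active, weights=weights, chi2=chi2,
                            scale=mu, offset=c,
                            repeat_chi2=np.array(repeat_chi2))


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def ensemble_stats(solution: EnsembleSolution, pool: CurvePool,
                   n_bins: int = 12) -> dict:
    """Weighted Rg/Dmax distributions, topology fractions and a
    flexibility index.

    The flexibility index is the Shannon entropy of the weighted Rg
    histogram of the selected ensemble divided by the entropy of the whole
    pool's Rg histogram (0 = single conformer, ~1 = as broad as the pool).
    It is an entropy surrogate for ensemble breadth, not the Rflex metric
    of any external package.
    """
    idx = np.array(sorted(solution.weights))
    w = np.array([solution.weights[int(i)] for i in idx])
    rg_sel = pool.rg_model[idx]
    edges = np.histogram_bin_edges(pool.rg_model, bins=n_bins)
    h_sel, _ = np.histogram(rg_sel, bins=edges, weights=w)
    h_pool, _ = np.histogram(pool.rg_model, bins=edges)

    def entropy(h):
        p = h / h.sum() if h.sum() > 0 else h
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    e_pool = entropy(h_pool.astype(float))
    flex = entropy(h_sel) / e_pool if e_pool > 0 else 0.0

    tags = {}
    for i, wi in zip(idx, w):
        tag = pool.topology_tags[int(i)]
        tags[tag] = tags.get(tag, 0.0) + wi
    return {
        "rg_edges": edges,
        "rg_hist": h_sel,
        "rg_hist_pool": h_pool,
        "rg_mean": float(np.sum(w * rg_sel)),
        "dmax_mean": float(np.sum(w * pool.dmax_model[idx])),
        "topology_fractions": tags,
        "flexibility_index": float(flex),
    }
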