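"""Eco-evolutionary optimality: the trait combination a climate selects for.

For a cell's monthly climate and ambient CO2, find the (C_leaf, a_ll,
phenology) combination and the maximum sustainable height that maximise
net carbon gain (NCG), the model's fitness measure.  Height is not a free
search dimension: every candidate is evaluated at its own maximum
potential height, the height at which NCG/NPP falls to ~0.2 (the minimum
surplus assumed necessary for reproduction), which couples the height and
carbon-gain criteria into one scalar objective.

The global search is a seeded differential-evolution algorithm,
vectorised over both the population and an arbitrary batch of cells so
the grid engine can optimise a whole landscape per forcing level in one
call.  Deciduousness is searched as a separate phenology case wherever
the climate has more than three months below 3 degC, and the better
phenology wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import OptimiserParams, PhysiologyParams
from .physiology import annual_balance_arrays

logger = logging.getLogger(__name__)

__all__ = ["TraitTarget", "CellClimate", "optimise_traits",
           "optimise_traits_batch", "max_potential_height",
           "deciduousness_allowed"]


@dataclass
class CellClimate:
    """Monthly climate of one grid cell."""

    t_monthly: np.ndarray      # degC, length 12
    p_monthly: np.ndarray      # mm month-1
    rsds_monthly: np.ndarray   # W m-2
    lat: float                 # degrees

    def __post_init__(self):
        for name in ("t_monthly", "p_monthly", "rsds_monthly"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (12,):
                raise ValueError(f"{name} must have 12 monthly values")
            setattr(self, name, arr)


@dataclass
class TraitTarget:
    """Optimiser output: the locally optimal reference plant."""

    c_leaf_target: float       # g C
    a_ll_target: float         # yr
    phenology_target: int      # 0 deciduous, 1 evergreen
    h_max: float               # m
    ncg_at_opt: float          # g C m-2 yr-1
    npp_at_opt: float
    viable: bool               # any searched candidate with NCG > 0
    converged: bool = True


def deciduousness_allowed(t_monthly, params: PhysiologyParams):
    """True where the climate has more than the required number of months
    with mean temperature below the growing threshold (3 degC)."""
    t = np.asarray(t_monthly, dtype=float)
    n_cold = np.sum(t < params.t_grow, axis=-1)
    return n_cold > params.months_cold_deciduous


def _local_niche(t_m):
    """Niche triple equal to the local climate (a perfectly adapted plant)."""
    return t_m.min(axis=-1), t_m.max(axis=-1), t_m.mean(axis=-1)


def _evaluate_at_height(h, c_leaf, a_ll, dec, t_m, p_m, r_m, lat, p_a,
                        params, lam_iters, niche=None):
    niche = _local_niche(t_m) if niche is None else niche
    return annual_balance_arrays(
        h, c_leaf, a_ll, dec, params.root_shoot, *niche,
        t_m, p_m, r_m, lat, p_a, params, lam_iters=lam_iters)


def _height_and_ncg(c_leaf, a_ll, dec, t_m, p_m, r_m, lat, p_a, params,
                    h_iters, lam_iters, niche=None, n_scan=6):
    """Vectorised maximum-height rule plus NCG/NPP at that height.

    Bisection on H for NCG/NPP = ratio target; the ratio declines with
    height because woody turnover and sapwood respiration costs grow
    faster than light capture.  If the ratio still exceeds the target at
    the upper height bound, the bound is returned; if it is already below
    at the lowest height, the candidate is non-viable and evaluated there.
    """
    ev = lambda h: _evaluate_at_height(h, c_leaf, a_ll, dec, t_m, p_m, r_m,
                                       lat, p_a, params, lam_iters, niche)
    target = params.ncg_npp_ratio

    def ratio_of(out):
        npp = out["npp"]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(npp > 0, out["ncg"] / np.where(npp > 0, npp, 1.0),
                         -np.inf)
        return r

    shape = np.broadcast(np.asarray(c_leaf), np.asarray(a_ll)).shape
    # the ratio is hump-shaped in H (leaf turnover dominates tiny plants,
    # hydraulics and woody turnover tall ones): locate the peak on a coarse
    # geometric grid, then bisect the descending branch for ratio = target
    h_scan = np.geomspace(params.h_min, params.h_max, n_scan)
    ratios = np.stack([ratio_of(ev(np.full(shape, hs))) for hs in h_scan])
    i_peak = ratios.argmax(axis=0)
    r_peak = np.take_along_axis(ratios, i_peak[None], axis=0)[0]
    h_peak = h_scan[i_peak]
    r_hi = ratios[-1]

    at_top = r_hi >= target          # canopy bound reached, ratio still ample
    dead_low = r_peak < target       # not sustainable at any height
    b_lo = h_peak.astype(float)
    b_hi = np.full(shape, params.h_max)
    for _ in range(h_iters):
        mid = 0.5 * (b_lo + b_hi)
        r_mid = ratio_of(ev(mid))
        go_up = r_mid >= target
        b_lo = np.where(go_up, mid, b_lo)
        b_hi = np.where(go_up, b_hi, mid)
    h = np.where(at_top, params.h_max,
                 np.where(dead_low, h_peak, 0.5 * (b_lo + b_hi)))
    out = ev(h)
    return h, out, dead_low


def max_potential_height(c_leaf, a_ll, deciduous, climate_cell: CellClimate,
                         p_a: float, params: PhysiologyParams | None = None,
                         h_iters: int = 14, lam_iters: int = 60, niche=None):
    """Maximum sustainable height for one trait combination.

    Returns ``(h_max, viable)``: the height at which NCG/NPP reaches the
    reproduction threshold (~0.2) to within the configured tolerance, and
    whether the plant sustains a positive NCG there.  ``niche`` optionally
    supplies the plant's own climatic niche triple (default: locally
    adapted).
    """
    params = params or PhysiologyParams()
    h, out, dead_low = _height_and_ncg(
        np.asarray(c_leaf, float), np.asarray(a_ll, float), bool(deciduous),
        climate_cell.t_monthly, climate_cell.p_monthly,
        climate_cell.rsds_monthly, climate_cell.lat, p_a, params,
        h_iters, lam_iters, niche=niche)
    viable = bool((out["ncg"] > 0) & (out["npp"] > 0) & ~dead_low)
    return float(h), viable


# ---------------------------------------------------------------------------
# vectorised differential evolution
# ---------------------------------------------------------------------------

def _differential_evolution(objective, lo, hi, n_prob, rng,
                            opt: OptimiserParams, init=None):
    """Maximise ``objective(x)`` with x of shape (n_prob, NP, D).

    DE/rand/1/bin with fixed generation count (deterministic given the
    rng state).  ``init`` optionally supplies the initial population.
    Returns (best_x (n_prob, D), best_f (n_prob,)).
    """
    d = lo.size
    np_ = opt.popsize
    pop = init if init is not None \
        else lo + (hi - lo) * rng.random((n_prob, np_, d))
    pop = np.clip(pop, lo, hi)
    fit = objective(pop)
    for _ in range(opt.generations):
        perm = rng.random((n_prob, np_)).argsort(axis=-1)
        r1 = np.take_along_axis(pop, perm[..., None], axis=1)
        r2 = np.take_along_axis(pop, np.roll(perm, 1, axis=-1)[..., None], axis=1)
        r3 = np.take_along_axis(pop, np.roll(perm, 2, axis=-1)[..., None], axis=1)
        mutant = np.clip(r1 + opt.mutation * (r2 - r3), lo, hi)
        cross = rng.random((n_prob, np_, d)) < opt.recombination
        jrand = rng.integers(0, d, size=(n_prob, np_))
        cross[np.arange(n_prob)[:, None], np.arange(np_)[None, :], jrand] = True
        trial = np.where(cross, mutant, pop)
        f_trial = objective(trial)
        better = f_trial > fit
        pop = np.where(better[..., None], trial, pop)
        fit = np.where(better, f_trial, fit)
    best = fit.argmax(axis=-1)
    ar = np.arange(n_prob)
    return pop[ar, best], fit[ar, best]


def _pattern_polish(objective, x0, f0, lo, hi, iters: int = 120):
    """Deterministic multi-start pattern-search refinement.

    ``x0``/``f0`` carry several starting points per problem,
    (n_prob, S, d) / (n_prob, S).  Each start evaluates axis-aligned and
    diagonal steps (the objective ridge is a narrow curved valley, so
    diagonal moves matter), takes the best improving neighbour, grows the
    step on success and halves it when stuck.  Returns the best point per
    problem; with a fixed start lattice this makes the found optimum
    insensitive to the search-space parameterisation.
    """
    d = lo.size
    n_prob, n_start = x0.shape[0], x0.shape[1]
    x = x0.copy()
    f = f0.copy()
    step = np.tile(0.05 * (hi - lo), (n_prob, n_start, 1))
    eye = np.eye(d)
    diag = np.array(np.meshgrid(*([[-1.0, 1.0]] * d))).T.reshape(-1, d)
    offsets = np.concatenate([eye, -eye, diag], axis=0)      # (K, d)
    k = offsets.shape[0]
    max_step = hi - lo
    for _ in range(iters):
        cand = np.clip(x[:, :, None, :] + step[:, :, None, :]
                       * offsets[None, None], lo, hi)        # (n, S, K, d)
        fc = objective(cand.reshape(n_prob, n_start * k, d)) \
            .reshape(n_prob, n_start, k)
        j = fc.argmax(axis=-1)
        fbest = np.take_along_axis(fc, j[..., None], axis=-1)[..., 0]
        xbest = np.take_along_axis(cand, j[..., None, None], axis=2)[:, :, 0]
        better = fbest > f
        x = np.where(better[..., None], xbest, x)
        f = np.where(better, fbest, f)
        step = np.where(better[..., None],
                        np.minimum(step * 1.6, 0.1 * max_step), step * 0.5)
    i = f.argmax(axis=-1)
    ar = np.arange(n_prob)
    return x[ar, i], f[ar, i]


def _phenology_search(dec: bool, t_m, p_m, r_m, lat, p_a, phys, opt,
                      h_iters, lam_iters, seed_tag, a_ll_scale, n_scan=4,
                      polish_starts=1, polish_iters=40, robust=False):
    """Global trait search for one phenology over a batch of cells.

    A seeded differential evolution in the requested axis parameterisation
    (``robust=True`` additionally searches the complementary axis scaling
    and keeps the better result), followed by a deterministic multi-start
    pattern polish in canonical log-log coordinates.  The combination
    makes the found optimum insensitive to the axis parameterisation.
    """
    n_prob = t_m.shape[0]
    a_hi = min(phys.a_ll_max, 1.0) if dec else phys.a_ll_max
    tm = t_m[:, None, :]
    pm = p_m[:, None, :]
    rm = r_m[:, None, :]
    la = lat[:, None]

    def objective_phys(c_leaf, a_ll):
        _, out, _ = _height_and_ncg(c_leaf, a_ll, dec, tm, pm, rm, la, p_a,
                                    phys, h_iters, lam_iters, n_scan=n_scan)
        return out["ncg"]

    log_lo = np.array([np.log10(opt.c_leaf_lo), np.log10(phys.a_ll_min)])
    log_hi = np.array([np.log10(opt.c_leaf_hi), np.log10(a_hi)])

    scales = ("log", "linear") if robust else (a_ll_scale,)
    if a_ll_scale not in scales:
        scales = scales + (a_ll_scale,)
    best_log_x = None
    best_f = None
    for i_sc, sc in enumerate(sorted(set(scales))):
        if sc == "log":
            lo = log_lo
            hi = log_hi
            to_all = lambda u: 10.0 ** u
        else:
            lo = np.array([np.log10(opt.c_leaf_lo), phys.a_ll_min])
            hi = np.array([np.log10(opt.c_leaf_hi), a_hi])
            to_all = lambda u: u
        objective = lambda x: objective_phys(10.0 ** x[..., 0],
                                             to_all(x[..., 1]))
        rng = np.random.default_rng(
            np.random.SeedSequence([opt.seed_const, seed_tag, int(dec),
                                    i_sc]))
        # initial design log-uniform in the physical trait space
        u = rng.random((n_prob, opt.popsize, 2))
        cl_init = log_lo[0] + u[..., 0] * (log_hi[0] - log_lo[0])
        al_phys = 10.0 ** (log_lo[1] + u[..., 1] * (log_hi[1] - log_lo[1]))
        al_init = np.log10(al_phys) if sc == "log" else al_phys
        init = np.stack([cl_init, al_init], axis=-1)
        bx, bf = _differential_evolution(objective, lo, hi, n_prob, rng,
                                         opt, init=init)
        bx_log = np.stack([bx[:, 0], np.log10(to_all(bx[:, 1]))], axis=-1)
        if best_f is None:
            best_log_x, best_f = bx_log, bf
        else:
            take = bf > best_f
            best_log_x = np.where(take[:, None], bx_log, best_log_x)
            best_f = np.where(take, bf, best_f)

    # deterministic polish in canonical log-log coordinates from the DE
    # winner plus a fixed lattice of starting points
    objective_log = lambda xl: objective_phys(10.0 ** xl[..., 0],
                                              10.0 ** xl[..., 1])
    starts = [best_log_x]
    if polish_starts > 1:
        side = int(np.ceil(np.sqrt(polish_starts - 1)))
        fr = (np.arange(side) + 0.5) / side
        for fa in fr:
            for fb in fr:
                pt = log_lo + np.array([fa, fb]) * (log_hi - log_lo)
                starts.append(np.tile(pt, (n_prob, 1)))
    x0 = np.stack(starts, axis=1)                       # (n_prob, S, d)
    f0 = objective_log(x0)
    x_log, _ = _pattern_polish(objective_log, x0, f0, log_lo, log_hi,
                               iters=polish_iters)
    c_leaf = 10.0 ** x_log[:, 0]
    a_ll = 10.0 ** x_log[:, 1]
    # refine the winner at full height/water precision
    h, out, dead_low = _height_and_ncg(
        c_leaf, a_ll, dec, t_m, p_m, r_m, lat, p_a, phys,
        h_iters=max(h_iters, 14), lam_iters=max(lam_iters, 60), n_scan=6)
    return {"c_leaf": c_leaf, "a_ll": a_ll, "h": h, "ncg": out["ncg"],
            "npp": out["npp"], "dead_low": dead_low}


def optimise_traits_batch(t_m, p_m, rsds_m, lat, p_a,
                          phys: PhysiologyParams | None = None,
                          opt: OptimiserParams | None = None,
                          seed: int | None = None,
                          h_iters: int = 10, lam_iters: int = 24,
                          a_ll_scale: str = "log", n_scan: int = 4,
                          polish_starts: int = 1, polish_iters: int = 40,
                          robust: bool = False):
    """Optimal trait targets for a batch of cells (arrays shaped (n, 12)).

    Returns a dict of arrays over cells: c_leaf, a_ll, deciduous, h_max,
    ncg, npp, viable.  Deterministic: the DE seed derives from a fixed
    constant, the CO2 level and the phenology case (``seed`` overrides
    the CO2 tag), so the optimum is a function of the environment alone.
    """
    phys = phys or PhysiologyParams()
    opt = opt or OptimiserParams()
    t_m = np.atleast_2d(np.asarray(t_m, float))
    p_m = np.atleast_2d(np.asarray(p_m, float))
    rsds_m = np.atleast_2d(np.asarray(rsds_m, float))
    lat = np.atleast_1d(np.asarray(lat, float))
    seed_tag = int(round(p_a * 100)) if seed is None else int(seed)

    ever = _phenology_search(False, t_m, p_m, rsds_m, lat, p_a, phys, opt,
                             h_iters, lam_iters, seed_tag, a_ll_scale, n_scan,
                             polish_starts, polish_iters, robust)
    result = {k: np.array(v, copy=True) for k, v in ever.items()}
    result["deciduous"] = np.zeros(t_m.shape[0], dtype=bool)

    allowed = deciduousness_allowed(t_m, phys)
    if np.any(allowed):
        sub = np.nonzero(allowed)[0]
        dec = _phenology_search(True, t_m[sub], p_m[sub], rsds_m[sub],
                                lat[sub], p_a, phys, opt, h_iters, lam_iters,
                                seed_tag, a_ll_scale, n_scan,
                                polish_starts, polish_iters, robust)
        take_sub = dec["ncg"] > ever["ncg"][sub]
        take = np.zeros(t_m.shape[0], dtype=bool)
        take[sub[take_sub]] = True
        for k in ("c_leaf", "a_ll", "h", "ncg", "npp", "dead_low"):
            result[k][sub[take_sub]] = dec[k][take_sub]
        result["deciduous"] = take

    # viability follows the fitness measure: some candidate sustains a
    # positive carbon surplus (cells whose ratio never reaches the
    # reproduction threshold live at their peak-ratio height instead)
    result.pop("dead_low")
    result["viable"] = (result["ncg"] > 0) & (result["npp"] > 0)
    return result


def optimise_traits(climate_cell: CellClimate, p_a: float,
                    bounds: dict | None = None, seed: int | None = None,
                    phys: PhysiologyParams | None = None,
                    opt: OptimiserParams | None = None,
                    h_iters: int = 14, lam_iters: int = 60,
                    a_ll_scale: str = "log") -> TraitTarget:
    """Optimal traits for a single cell (scalar convenience API).

    Searches at full height/water precision with a generous DE budget
    (the batch API trades some of that for throughput).  ``bounds`` may
    override the c_leaf search range as ``{"c_leaf": (lo, hi)}``.
    Deterministic given ``seed``.
    """
    from dataclasses import replace as _replace
    phys = phys or PhysiologyParams()
    opt = opt or OptimiserParams()
    opt = _replace(opt, popsize=max(opt.popsize, 24),
                   generations=max(opt.generations, 60))
    if bounds and "c_leaf" in bounds:
        lo, hi = bounds["c_leaf"]
        from dataclasses import replace
        opt = replace(opt, c_leaf_lo=lo, c_leaf_hi=hi)
    res = optimise_traits_batch(
        climate_cell.t_monthly[None, :], climate_cell.p_monthly[None, :],
        climate_cell.rsds_monthly[None, :], np.array([climate_cell.lat]),
        p_a, phys, opt, seed=seed, h_iters=h_iters, lam_iters=lam_iters,
        a_ll_scale=a_ll_scale, n_scan=6, polish_starts=10, polish_iters=120,
        robust=True)
    return TraitTarget(
        c_leaf_target=float(res["c_leaf"][0]),
        a_ll_target=float(res["a_ll"][0]),
        phenology_target=0 if bool(res["deciduous"][0]) else 1,
        h_max=float(res["h"][0]),
        ncg_at_opt=float(res["ncg"][0]),
        npp_at_opt=float(res["npp"][0]),
        viable=bool(res["viable"][0]))
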