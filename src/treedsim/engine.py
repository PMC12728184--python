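"""Spatially explicit eco-evolutionary time stepping.

Each coarse time step (10 kyr by default) executes four stages per land
cell: (1) the trait optimiser predicts the locally optimal reference
plant; (2) the incumbent's traits evolve a stochastic fraction
Normal(alpha, 0.05) of the way towards that target, its climatic niche
towards the local climate, and its height is re-derived from the maximum
potential height rule; (3) every plant draws a Weibull dispersal distance
and places trait-identical offspring in all land cells within range; (4)
a competition function keeps, per cell, the candidate with the best
height-penalised net carbon gain.  Global carbon and silicate-weathering
diagnostics are recorded every step.

Randomness is split into per-(step, purpose) child streams of the master
scenario seed; the trait optimum itself is a deterministic function of
the environment (see :mod:`treedsim.optimiser`), so optimisation targets
are cached per CO2 level and shared across scenarios on the same world.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .forcing import (ClimatologyGrid, Co2Schedule, cell_areas_km2,
                      interpolate_climatology, petm_co2_schedule,
                      synthetic_world)
from .optimiser import (CellClimate, TraitTarget, _height_and_ncg,
                        max_potential_height, optimise_traits_batch)
from .params import OptimiserParams, PhysiologyParams, WeatheringParams
from .physiology import PlantState, annual_balance_arrays, specific_leaf_area
from .weathering import (biomass_norm, calibrate_erosion_scale, co2_consumption,
                         erosion, silicate_weathering,
                         vegetation_weathering_factor, soil_carbon)

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "GridState", "Simulation", "run_simulation",
           "adapt_traits", "sample_dispersal", "disperse", "compete",
           "height_penalty", "PRESETS", "REGIONS"]

# scenario grid spanned in the reference experiment
PRESETS = {
    "slow-evolution-low-dispersal": dict(alpha=0.01, dispersal_scale=200.0),
    "slow-evolution-high-dispersal": dict(alpha=0.01, dispersal_scale=1100.0),
    "mid-evolution-mid-dispersal": dict(alpha=0.1, dispersal_scale=650.0),
    "fast-evolution-low-dispersal": dict(alpha=1.0, dispersal_scale=200.0),
    "fast-evolution-high-dispersal": dict(alpha=1.0, dispersal_scale=1100.0),
}

REGIONS = {"tropics": (0.0, 23.5), "temperate": (23.5, 50.0),
           "polar": (50.0, 90.0)}

_RNG_ADAPT, _RNG_DISPERSAL = 1, 2


@dataclass
class ScenarioConfig:
    """Full experiment description."""

    alpha: float = 1.0                  # adaptation rate in [0, 1]
    adapt_sd: float = 0.05              # sd of the stochastic adaptation draw
    dispersal_scale: float = 1100.0     # km per step (Weibull scale)
    dispersal_shape: float = 1.75
    k_nichebreadth: float = 0.03        # {0, 0.03, 0.10}
    co2_fertilisation: bool = True
    step_kyr: float = 10.0
    seed: int = 0
    co2_schedule: Co2Schedule = field(default_factory=Co2Schedule)
    # synthetic-world source (ignored when grids are passed explicitly)
    n_lat: int = 18
    n_lon: int = 36
    warming_offset: float = 8.0         # degC land-mean at peak
    world_seed: int = 42
    world_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if self.dispersal_scale <= 0 or self.dispersal_shape <= 0:
            raise ValueError("dispersal kernel parameters must be positive")


@dataclass
class GridState:
    """Per-land-cell reference plants (vectorised)."""

    occupied: np.ndarray        # bool (n_land,)
    height: np.ndarray
    c_leaf: np.ndarray
    a_ll: np.ndarray
    deciduous: np.ndarray       # bool
    niche_tmin: np.ndarray
    niche_tmax: np.ndarray
    niche_tmean: np.ndarray
    step_index: int = 0

    def copy(self) -> "GridState":
        return GridState(*(v.copy() if isinstance(v, np.ndarray) else v
                           for v in (self.occupied, self.height, self.c_leaf,
                                     self.a_ll, self.deciduous,
                                     self.niche_tmin, self.niche_tmax,
                                     self.niche_tmean, self.step_index)))


# ---------------------------------------------------------------------------
# elementary operations (scalar/spec surface + vectorised internals)
# ---------------------------------------------------------------------------

def _clipped_rates(rng, alpha, adapt_sd, size):
    """Normal(alpha, sd) adaptation fractions clipped into [0, 1]."""
    if adapt_sd == 0.0:
        return np.full(size, float(alpha))
    return np.clip(rng.normal(alpha, adapt_sd, size=size), 0.0, 1.0)


def adapt_traits(current: PlantState, target: TraitTarget,
                 local_climate: CellClimate, alpha: float, adapt_sd: float,
                 rng: np.random.Generator,
                 phys: PhysiologyParams | None = None,
                 p_a: float = 680.0) -> PlantState:
    """Evolve one plant a stochastic fraction towards the local optimum.

    C_leaf and a_ll move towards the optimiser target; the climatic niche
    moves towards the local coldest-month / warmest-month / mean annual
    temperature; each move is scaled by an independent draw from
    Normal(alpha, adapt_sd) clipped into [0, 1].  The plant turns
    deciduous iff deciduousness is favourable locally and the new leaf
    longevity is at most one year.  Height is fully dynamic: re-derived
    from the maximum-potential-height rule with the new traits.
    """
    phys = phys or PhysiologyParams()
    r = _clipped_rates(rng, alpha, adapt_sd, 5)
    c_leaf = current.c_leaf + r[0] * (target.c_leaf_target - current.c_leaf)
    a_ll = current.a_ll + r[1] * (target.a_ll_target - current.a_ll)
    t_m = local_climate.t_monthly
    tmin = current.t_min_veg + r[2] * (t_m.min() - current.t_min_veg)
    tmax = current.t_max_veg + r[3] * (t_m.max() - current.t_max_veg)
    tmean = current.t_mean_veg + r[4] * (t_m.mean() - current.t_mean_veg)
    tmean = min(max(tmean, tmin), tmax)
    deciduous = (target.phenology_target == 0) and (a_ll <= 1.0)
    h, _ = max_potential_height(c_leaf, a_ll, deciduous, local_climate,
                                p_a=p_a, params=phys,
                                niche=(tmin, tmax, tmean))
    return PlantState(height=h, c_leaf=c_leaf, a_ll=a_ll, deciduous=deciduous,
                      root_shoot=phys.root_shoot, t_min_veg=tmin,
                      t_max_veg=tmax, t_mean_veg=tmean)


def sample_dispersal(scale: float, shape: float, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw n Weibull dispersal distances (km)."""
    if scale <= 0:
        raise ValueError("dispersal scale must be positive")
    return scale * rng.weibull(shape, size=n)


def disperse(occupied_idx: np.ndarray, distances: np.ndarray,
             dist_matrix: np.ndarray):
    """Candidate (target_cell, source_cell) pairs after dispersal.

    Each plant places trait-identical offspring in every land cell whose
    centre lies within its drawn distance; the incumbent always remains a
    candidate in its own cell (distance zero).
    """
    reach = dist_matrix[occupied_idx, :] <= distances[:, None]
    reach[np.arange(occupied_idx.size), occupied_idx] = True
    src_pos, tgt = np.nonzero(reach)
    return tgt, occupied_idx[src_pos]


def height_penalty(height, mean_height, k_h: float = 0.2):
    """Logistic light-competition factor S(H; Hbar) in (0, 1)."""
    return 1.0 / (1.0 + np.exp(-k_h * (np.asarray(height, float)
                                       - np.asarray(mean_height, float))))


def compete(cand_cell: np.ndarray, cand_ncg: np.ndarray,
            cand_height: np.ndarray, n_cells: int, k_h: float = 0.2):
    """Select, per cell, the winner among positive-NCG candidates.

    Fitness is NCG scaled by a logistic height penalty around the mean
    height of the surviving candidates in the cell.  Returns the index of
    the winning candidate row per cell (-1 where no candidate has
    NCG > 0).  Permutation-invariant: candidates are processed in a
    canonical (cell, then input order) sort with fitness ties broken by
    larger height.
    """
    winner = np.full(n_cells, -1, dtype=int)
    pos = cand_ncg > 0
    if not np.any(pos):
        return winner
    idx = np.nonzero(pos)[0]
    cells = cand_cell[idx]
    order = np.argsort(cells, kind="stable")
    idx, cells = idx[order], cells[order]
    bounds = np.searchsorted(cells, np.arange(n_cells + 1))
    for c in np.unique(cells):
        rows = idx[bounds[c]:bounds[c + 1]]
        h = cand_height[rows]
        fitness = cand_ncg[rows] * height_penalty(h, h.mean(), k_h)
        best = np.lexsort((h, fitness))[-1]
        winner[c] = rows[best]
    return winner


# ---------------------------------------------------------------------------
# the simulation driver
# ---------------------------------------------------------------------------

class Simulation:
    """Drives one scenario on a (pre, peak) endmember world.

    ``target_cache`` maps (co2, k_nichebreadth, co2_fertilisation) to the
    optimiser targets for every land cell and may be shared between
    simulations on the same world to avoid recomputing identical optima.
    """

    def __init__(self, config: ScenarioConfig,
                 grids: tuple[ClimatologyGrid, ClimatologyGrid] | None = None,
                 phys: PhysiologyParams | None = None,
                 opt: OptimiserParams | None = None,
                 weath: WeatheringParams | None = None,
                 target_cache: dict | None = None,
                 h_iters: int = 10, lam_iters: int = 24):
        self.config = config
        base = phys or PhysiologyParams()
        self.phys = replace(base, k_nichebreadth=config.k_nichebreadth,
                            co2_fertilisation=config.co2_fertilisation)
        self.opt = opt or OptimiserParams()
        self.weath = weath or WeatheringParams()
        self.h_iters = h_iters
        self.lam_iters = lam_iters
        if grids is None:
            grids = synthetic_world(config.n_lat, config.n_lon,
                                    config.warming_offset, config.world_seed,
                                    config.world_params)
        self.pre, self.peak = grids
        if not self.pre.congruent_with(self.peak):
            raise ValueError("endmember grids are not congruent")

        mask = self.pre.land_mask
        self.land_i, self.land_j = np.nonzero(mask)
        self.n_land = self.land_i.size
        self.lat_cell = self.pre.lat[self.land_i]
        self.lon_cell = self.pre.lon[self.land_j]
        self.slope_cell = self.pre.slope[self.land_i, self.land_j]
        self.area_km2 = cell_areas_km2(self.pre)[self.land_i, self.land_j]
        self.dist_km = self._great_circle_matrix()
        self.target_cache = target_cache if target_cache is not None else {}
        self._climate_cache: dict = {}
        self.k_e: float | None = None
        self.omega_ref: float | None = None

    # -- geometry ----------------------------------------------------------
    def _great_circle_matrix(self) -> np.ndarray:
        lat = np.deg2rad(self.lat_cell)
        lon = np.deg2rad(self.lon_cell)
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = (np.sin(dlat / 2.0) ** 2
             + np.cos(lat)[:, None] * np.cos(lat)[None, :]
             * np.sin(dlon / 2.0) ** 2)
        return 2.0 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))

    # -- forcing -----------------------------------------------------------
    def climate_at(self, co2: float):
        """Land-cell climate arrays (t, p, rsds each (n_land, 12)) at a CO2."""
        key = round(float(co2), 6)
        if key not in self._climate_cache:
            grid = interpolate_climatology(self.pre, self.peak, co2)
            self._climate_cache[key] = tuple(
                arr[self.land_i, self.land_j, :]
                for arr in (grid.t_monthly, grid.p_monthly, grid.rsds_monthly))
        return self._climate_cache[key]

    def targets_at(self, co2: float) -> dict:
        """Optimiser targets for every land cell at a CO2 level (cached)."""
        key = (round(float(co2), 2), self.phys.k_nichebreadth,
               self.phys.co2_fertilisation)
        if key not in self.target_cache:
            t_m, p_m, r_m = self.climate_at(co2)
            self.target_cache[key] = optimise_traits_batch(
                t_m, p_m, r_m, self.lat_cell, co2, self.phys, self.opt,
                h_iters=self.h_iters, lam_iters=self.lam_iters)
        return self.target_cache[key]

    # -- state -------------------------------------------------------------
    def initialise(self) -> GridState:
        """One reference plant per land cell, optimally adapted to the
        pre-event climate (empty where nothing is viable)."""
        co2 = self.config.co2_schedule.co2_pre
        tgt = self.targets_at(co2)
        t_m, _, _ = self.climate_at(co2)
        return GridState(
            occupied=tgt["viable"].copy(),
            height=tgt["h"].copy(), c_leaf=tgt["c_leaf"].copy(),
            a_ll=tgt["a_ll"].copy(), deciduous=tgt["deciduous"].copy(),
            niche_tmin=t_m.min(axis=-1), niche_tmax=t_m.max(axis=-1),
            niche_tmean=t_m.mean(axis=-1), step_index=0)

    def _rng(self, step_index: int, purpose: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.config.seed) & 0x7FFFFFFF,
                                    step_index, purpose]))

    def _evaluate(self, cells, state_idx, state: GridState, co2: float,
                  heights=None):
        """Annual balance of plants ``state_idx`` placed into ``cells``."""
        t_m, p_m, r_m = self.climate_at(co2)
        h = state.height[state_idx] if heights is None else heights
        return annual_balance_arrays(
            h, state.c_leaf[state_idx], state.a_ll[state_idx],
            state.deciduous[state_idx], self.phys.root_shoot,
            state.niche_tmin[state_idx], state.niche_tmax[state_idx],
            state.niche_tmean[state_idx],
            t_m[cells], p_m[cells], r_m[cells], self.lat_cell[cells],
            co2, self.phys, lam_iters=self.lam_iters)

    # -- one step ----------------------------------------------------------
    def step(self, state: GridState, co2: float) -> GridState:
        cfg = self.config
        t_m, p_m, r_m = self.climate_at(co2)
        tgt = self.targets_at(co2)
        occ = np.nonzero(state.occupied)[0]
        new = state.copy()
        new.step_index = state.step_index + 1

        if occ.size:
            # (2) stochastic evolutionary adaptation towards the targets
            rng = self._rng(state.step_index, _RNG_ADAPT)
            rates = _clipped_rates(rng, cfg.alpha, cfg.adapt_sd, (5, occ.size))
            new.c_leaf[occ] += rates[0] * (tgt["c_leaf"][occ] - new.c_leaf[occ])
            new.a_ll[occ] += rates[1] * (tgt["a_ll"][occ] - new.a_ll[occ])
            new.niche_tmin[occ] += rates[2] * (t_m[occ].min(axis=-1)
                                               - new.niche_tmin[occ])
            new.niche_tmax[occ] += rates[3] * (t_m[occ].max(axis=-1)
                                               - new.niche_tmax[occ])
            new.niche_tmean[occ] += rates[4] * (t_m[occ].mean(axis=-1)
                                                - new.niche_tmean[occ])
            new.niche_tmean[occ] = np.clip(new.niche_tmean[occ],
                                           new.niche_tmin[occ],
                                           new.niche_tmax[occ])
            new.deciduous[occ] = tgt["deciduous"][occ] & (new.a_ll[occ] <= 1.0)

            # (3) dispersal
            rng_d = self._rng(state.step_index, _RNG_DISPERSAL)
            dist = sample_dispersal(cfg.dispersal_scale, cfg.dispersal_shape,
                                    occ.size, rng_d)
            cand_cell, cand_src = disperse(occ, dist, self.dist_km)

            # (4) competition on height-penalised NCG.  Candidates are the
            # adapted plants (incumbent plus trait-identical offspring
            # within dispersal range) and, in its own cell, the
            # pre-adaptation incumbent: selection never fixes a trait move
            # that lowers fitness in place.  Height is fully dynamic, so
            # every candidate is evaluated at its maximum potential height
            # in the destination cell.
            fields = ("c_leaf", "a_ll", "deciduous", "niche_tmin",
                      "niche_tmax", "niche_tmean")
            cand = {f: np.concatenate([getattr(new, f)[cand_src],
                                       getattr(state, f)[occ]])
                    for f in fields}
            cells = np.concatenate([cand_cell, occ])
            niche = (cand["niche_tmin"], cand["niche_tmax"],
                     cand["niche_tmean"])
            cand_h, bal, _ = _height_and_ncg(
                cand["c_leaf"], cand["a_ll"], cand["deciduous"],
                t_m[cells], p_m[cells], r_m[cells], self.lat_cell[cells],
                co2, self.phys, self.h_iters, self.lam_iters, niche=niche,
                n_scan=4)
            win = compete(cells, bal["ncg"], cand_h, self.n_land)
            has = win >= 0
            row = np.maximum(win, 0)
            for name in fields:
                arr = getattr(new, name)
                arr[:] = np.where(has, cand[name][row], arr)
            new.height = np.where(has, cand_h[row], new.height)
            new.occupied = has
        else:
            new.occupied = np.zeros(self.n_land, dtype=bool)
        return new

    # -- diagnostics -------------------------------------------------------
    def compute_diagnostics(self, state: GridState, co2: float) -> dict:
        """Global stocks/fluxes as a pure function of (state, forcing)."""
        t_m, p_m, r_m = self.climate_at(co2)
        area_m2 = self.area_km2 * 1e6
        t_mean = t_m.mean(axis=-1)
        p_ann = p_m.sum(axis=-1)

        biomass_dens = np.zeros(self.n_land)       # g C m-2 ground
        npp = np.zeros(self.n_land)
        aet_ann = np.zeros(self.n_land)
        occ = np.nonzero(state.occupied)[0]
        if occ.size:
            bal = self._evaluate(occ, occ, state, co2)
            total_pool = (state.c_leaf[occ] + bal["c_sapwood"]
                          + bal["c_heartwood"] + bal["c_coarseroot"]
                          + bal["c_fineroot"])
            biomass_dens[occ] = total_pool / bal["crown_area"]
            npp[occ] = np.maximum(bal["npp"], 0.0)
            aet_ann[occ] = bal["aet_annual"]

        q = np.maximum(p_ann - aet_ann, 0.0)       # runoff proxy, mm yr-1
        if self.k_e is None:
            self.k_e = calibrate_erosion_scale(q, self.slope_cell, t_mean,
                                               self.area_km2, self.weath)
        eps = erosion(q, self.slope_cell, t_mean, k_e=self.k_e,
                      params=self.weath)
        bm_norm = biomass_norm(biomass_dens * 0.01, params=self.weath)
        f_bm = vegetation_weathering_factor(bm_norm, params=self.weath)
        omega = silicate_weathering(eps, q, t_mean + 273.15, f_bm,
                                    params=self.weath)
        omega_global = float(np.sum(omega * area_m2))
        if self.omega_ref is None:
            self.omega_ref = omega_global
        f_silw = co2_consumption(omega_global, self.omega_ref,
                                 params=self.weath)

        soil = soil_carbon(npp, t_mean, self.weath)
        row = {
            "n_occupied": int(state.occupied.sum()),
            "biomass_PgC": float(np.sum(biomass_dens * area_m2) / 1e15),
            "soil_PgC": float(np.sum(soil * area_m2) / 1e15),
            "npp_PgC_yr": float(np.sum(npp * area_m2) / 1e15),
            "weathering_molC_yr": f_silw,
        }
        lma = np.where(state.occupied,
                       1.0 / (specific_leaf_area(np.maximum(state.a_ll, 1e-6))
                              * 1.0), np.nan)  # g C m-2 leaf
        for region, (lo, hi) in REGIONS.items():
            sel = state.occupied & (np.abs(self.lat_cell) >= lo) \
                & (np.abs(self.lat_cell) < hi)
            w = self.area_km2[sel]
            if sel.any():
                row[f"height_{region}"] = float(
                    np.average(state.height[sel], weights=w))
                row[f"lma_{region}"] = float(np.average(lma[sel], weights=w))
                row[f"phenology_{region}"] = float(
                    np.average(1.0 - state.deciduous[sel], weights=w))
            else:
                row[f"height_{region}"] = np.nan
                row[f"lma_{region}"] = np.nan
                row[f"phenology_{region}"] = np.nan
        occ_any = state.occupied.any()
        row["mean_height_m"] = float(
            np.average(state.height[state.occupied],
                       weights=self.area_km2[state.occupied])) if occ_any else np.nan
        row["mean_lma_g_m2"] = float(
            np.average(lma[state.occupied],
                       weights=self.area_km2[state.occupied])) if occ_any else np.nan
        return row

    # -- state snapshots -----------------------------------------------------
    def state_dataset(self, state: GridState, co2: float):
        """Per-cell traits and fluxes of a state as an xarray Dataset
        (writable as a NetCDF snapshot via ``.to_netcdf(engine='scipy')``)."""
        import xarray as xr
        occ = np.nonzero(state.occupied)[0]
        npp = np.full(self.n_land, np.nan)
        ncg = np.full(self.n_land, np.nan)
        if occ.size:
            bal = self._evaluate(occ, occ, state, co2)
            npp[occ] = bal["npp"]
            ncg[occ] = bal["ncg"]
        data = {
            "occupied": ("cell", state.occupied.astype(np.int8)),
            "height": ("cell", state.height),
            "c_leaf": ("cell", state.c_leaf),
            "a_ll": ("cell", state.a_ll),
            "deciduous": ("cell", state.deciduous.astype(np.int8)),
            "niche_tmin": ("cell", state.niche_tmin),
            "niche_tmax": ("cell", state.niche_tmax),
            "niche_tmean": ("cell", state.niche_tmean),
            "npp": ("cell", npp),
            "ncg": ("cell", ncg),
        }
        return xr.Dataset(
            data,
            coords={"cell": np.arange(self.n_land),
                    "lat_cell": ("cell", self.lat_cell),
                    "lon_cell": ("cell", self.lon_cell)},
            attrs={"co2_ppm": float(co2),
                   "step_index": int(state.step_index)})

    # -- full run ----------------------------------------------------------
    def timeline_kyr(self) -> np.ndarray:
        s = self.config.co2_schedule
        step = self.config.step_kyr
        return np.arange(-s.t_pre, s.t_end + 0.5 * step, step)

    def run(self) -> pd.DataFrame:
        """Execute the full timeline; returns the diagnostics series."""
        sched = self.config.co2_schedule
        times = self.timeline_kyr()
        state = self.initialise()
        rows = []
        for i, t in enumerate(times):
            tic = time.perf_counter()
            co2 = petm_co2_schedule(float(t), sched)
            if i > 0:
                state = self.step(state, co2)
            row = {"step": i, "time_kyr": float(t), "co2": co2}
            row.update(self.compute_diagnostics(state, co2))
            rows.append(row)
            logger.info("step %d (t=%+.0f kyr, CO2=%.0f ppm): %d occupied, "
                        "%.2f s", i, t, co2, row["n_occupied"],
                        time.perf_counter() - tic)
        self.final_state = state
        return pd.DataFrame(rows)


def run_simulation(config: ScenarioConfig, grids=None, target_cache=None,
                   **kwargs) -> pd.DataFrame:
    """Run one scenario end to end; returns the diagnostics DataFrame.

    The returned frame carries the scenario metadata in ``attrs``.
    """
    sim = Simulation(config, grids=grids, target_cache=target_cache, **kwargs)
    series = sim.run()
    series.attrs["config"] = asdict(config)
    series.attrs["k_e"] = sim.k_e
    series.attrs["omega_ref"] = sim.omega_ref
    return series
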