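"""Tests for the eco-evolutionary grid engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gamma as gamma_fn

from treedsim.engine import (PRESETS, ScenarioConfig, Simulation,
                             adapt_traits, compete, disperse, height_penalty,
                             run_simulation, sample_dispersal)
from treedsim.forcing import Co2Schedule, synthetic_world
from treedsim.optimiser import CellClimate, TraitTarget, optimise_traits
from treedsim.params import OptimiserParams, PhysiologyParams, with_overrides
from treedsim.physiology import PlantState, annual_carbon_balance

from conftest import make_climate

FAST = dict(opt=OptimiserParams(popsize=12, generations=18),
            h_iters=8, lam_iters=12)


@pytest.fixture(scope="module")
def small_world():
    return synthetic_world(8, 16, 8.0, 7)


def _short_config(**kw):
    sched = Co2Schedule(t_pre=20.0, body_duration=20.0, t_recovery1=60.0,
                        t_end=80.0)
    base = dict(alpha=1.0, dispersal_scale=900.0, seed=3, co2_schedule=sched,
                n_lat=8, n_lon=16, world_seed=7)
    base.update(kw)
    return ScenarioConfig(**base)


# ---------------------------------------------------------------------------
# adaptation
# ---------------------------------------------------------------------------

def _target():
    return TraitTarget(c_leaf_target=4000.0, a_ll_target=1.5,
                       phenology_target=1, h_max=20.0, ncg_at_opt=300.0,
                       npp_at_opt=1500.0, viable=True)


def test_adapt_full_rate_reaches_target(temperate_climate, phys):
    current = PlantState(10.0, 1000.0, 0.5, False, 1.0, -5.0, 25.0, 10.0)
    rng = np.random.default_rng(0)
    new = adapt_traits(current, _target(), temperate_climate, alpha=1.0,
                       adapt_sd=0.0, rng=rng, phys=phys)
    assert new.c_leaf == pytest.approx(4000.0)
    assert new.a_ll == pytest.approx(1.5)
    assert new.t_min_veg == pytest.approx(temperate_climate.t_monthly.min())
    assert new.t_max_veg == pytest.approx(temperate_climate.t_monthly.max())
    assert new.t_mean_veg == pytest.approx(temperate_climate.t_monthly.mean())


def test_adapt_zero_rate_is_identity(temperate_climate, phys):
    current = PlantState(10.0, 1000.0, 0.5, False, 1.0, -5.0, 25.0, 10.0)
    rng = np.random.default_rng(0)
    new = adapt_traits(current, _target(), temperate_climate, alpha=0.0,
                       adapt_sd=0.0, rng=rng, phys=phys)
    assert new.c_leaf == current.c_leaf
    assert new.a_ll == current.a_ll
    assert new.t_mean_veg == current.t_mean_veg


def test_adapt_rate_distribution_recovery():
    """The realised step fraction averages to alpha (Normal(alpha, 0.05)
    draws, clipping negligible away from the boundaries)."""
    from treedsim.engine import _clipped_rates
    rng = np.random.default_rng(12)
    alpha, sd, n = 0.3, 0.05, 10_000
    r = _clipped_rates(rng, alpha, sd, n)
    assert abs(r.mean() - alpha) <= 3.0 * sd / np.sqrt(n)
    assert np.all((r >= 0.0) & (r <= 1.0))


def test_adapt_deciduous_switch_rule(boreal_climate, phys):
    """Deciduousness requires both a favourable target phenology and a new
    leaf longevity of at most one year."""
    tgt = TraitTarget(2000.0, 0.6, 0, 10.0, 200.0, 1000.0, True)
    current = PlantState(8.0, 2000.0, 0.6, False, 1.0,
                         boreal_climate.t_monthly.min(),
                         boreal_climate.t_monthly.max(),
                         boreal_climate.t_monthly.mean())
    rng = np.random.default_rng(1)
    new = adapt_traits(current, tgt, boreal_climate, 1.0, 0.0, rng, phys)
    assert new.deciduous
    tgt_long = TraitTarget(2000.0, 3.0, 0, 10.0, 200.0, 1000.0, True)
    new2 = adapt_traits(current, tgt_long, boreal_climate, 1.0, 0.0, rng,
                        phys)
    assert not new2.deciduous          # a_ll,new > 1 keeps it evergreen


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------

def test_weibull_kernel_moments():
    rng = np.random.default_rng(100)
    scale, shape, n = 800.0, 1.75, 100_000
    d = sample_dispersal(scale, shape, n, rng)
    assert np.all(d >= 0.0)
    mean_expected = scale * gamma_fn(1.0 + 1.0 / shape)
    se = d.std(ddof=1) / np.sqrt(n)
    assert abs(d.mean() - mean_expected) <= 3.0 * se
    p = 1.0 - np.exp(-1.0)
    p_hat = np.mean(d <= scale)
    assert abs(p_hat - p) <= 3.0 * np.sqrt(p * (1 - p) / n)


def test_dispersal_rejects_bad_scale():
    with pytest.raises(ValueError):
        sample_dispersal(0.0, 1.75, 10, np.random.default_rng(0))


def test_disperse_on_uniform_transect():
    """Drawn distance 2.5 cell spacings colonises exactly 2 cells each side."""
    n = 11
    d = 100.0
    dist = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]) * d
    tgt, src = disperse(np.array([5]), np.array([2.5 * d]), dist)
    assert sorted(tgt.tolist()) == [3, 4, 5, 6, 7]
    assert np.all(src == 5)
    # below nearest-neighbour spacing: only the home cell
    tgt, src = disperse(np.array([5]), np.array([0.5 * d]), dist)
    assert tgt.tolist() == [5]


# ---------------------------------------------------------------------------
# competition
# ---------------------------------------------------------------------------

def test_compete_single_positive_candidate_wins():
    win = compete(np.array([2]), np.array([50.0]), np.array([10.0]), 4)
    assert win[2] == 0 and win[0] == -1


def test_compete_discards_nonpositive():
    win = compete(np.array([0, 0]), np.array([-5.0, 0.0]),
                  np.array([10.0, 20.0]), 1)
    assert win[0] == -1


def test_compete_equal_ncg_taller_wins():
    win = compete(np.array([0, 0]), np.array([100.0, 100.0]),
                  np.array([30.0, 10.0]), 1)
    assert win[0] == 0


def test_compete_permutation_invariant():
    rng = np.random.default_rng(4)
    cells = rng.integers(0, 5, 40)
    ncg = rng.normal(50, 60, 40)
    h = rng.uniform(1, 40, 40)
    win = compete(cells, ncg, h, 5)
    perm = rng.permutation(40)
    win_p = compete(cells[perm], ncg[perm], h[perm], 5)
    for c in range(5):
        a = (cells[win[c]], ncg[win[c]], h[win[c]]) if win[c] >= 0 else None
        b = (cells[perm][win_p[c]], ncg[perm][win_p[c]],
             h[perm][win_p[c]]) if win_p[c] >= 0 else None
        assert a == b


def test_height_penalty_logistic():
    assert height_penalty(20.0, 20.0) == pytest.approx(0.5)
    assert height_penalty(40.0, 20.0) > height_penalty(10.0, 20.0)


# ---------------------------------------------------------------------------
# the stepping engine
# ---------------------------------------------------------------------------

def test_initialisation_optimally_adapted(small_world):
    sim = Simulation(_short_config(), grids=small_world, **FAST)
    state = sim.initialise()
    assert state.occupied.any()
    t_m, _, _ = sim.climate_at(680.0)
    # niche equals the local climate everywhere (optimal adaptation)
    assert np.allclose(state.niche_tmin, t_m.min(axis=-1))
    assert np.allclose(state.niche_tmax, t_m.max(axis=-1))
    assert np.allclose(state.niche_tmean, t_m.mean(axis=-1))


def test_run_deterministic_given_seed(small_world):
    a = Simulation(_short_config(seed=9), grids=small_world, **FAST).run()
    b = Simulation(_short_config(seed=9), grids=small_world, **FAST).run()
    pd.testing.assert_frame_equal(a, b)


def test_constant_forcing_reaches_steady_state():
    """Under stationary climate the global biomass settles to a fixed
    point (step-to-step change < 1% after spin-up).  Uses the reference
    grid resolution: on very coarse grids single-cell competition churn
    is visible in the global stocks."""
    sched = Co2Schedule(t_pre=30.0, co2_peak=680.0 + 1e-9,
                        body_duration=30.0, t_recovery1=80.0,
                        co2_recovery1=680.0, t_end=100.0, co2_end=680.0)
    cfg = ScenarioConfig(alpha=1.0, adapt_sd=0.0, dispersal_scale=900.0,
                         seed=2, co2_schedule=sched, n_lat=18, n_lon=36,
                         world_seed=42)
    series = Simulation(cfg, h_iters=9, lam_iters=16).run()
    biomass = series["biomass_PgC"].values
    rel = np.abs(np.diff(biomass[-5:])) / biomass[-5:-1]
    assert np.all(rel < 0.01)


def test_frozen_dynamics_without_adaptation_or_dispersal(small_world):
    """alpha = 0, sd = 0 and a vanishing dispersal scale freeze the trait
    state; only climate-driven occupancy can change."""
    cfg = _short_config(alpha=0.0, adapt_sd=0.0, dispersal_scale=1e-6)
    sim = Simulation(cfg, grids=small_world, **FAST)
    state = sim.initialise()
    nxt = sim.step(state, 680.0)
    occ = state.occupied & nxt.occupied
    assert np.allclose(nxt.c_leaf[occ], state.c_leaf[occ])
    assert np.allclose(nxt.a_ll[occ], state.a_ll[occ])
    assert np.allclose(nxt.niche_tmean[occ], state.niche_tmean[occ])


def test_diagnostics_pure_function_of_state(small_world):
    sim = Simulation(_short_config(), grids=small_world, **FAST)
    state = sim.initialise()
    row1 = sim.compute_diagnostics(state, 680.0)
    row2 = sim.compute_diagnostics(state.copy(), 680.0)
    assert row1 == row2


def test_niche_breadth_monotone_stress(phys, temperate_climate):
    """Sharper niche limitation never raises carbon gain after a warming
    shock (same plant, same displaced climate)."""
    plant = PlantState(12.0, 3000.0, 1.2, False, 1.0,
                       temperate_climate.t_monthly.min(),
                       temperate_climate.t_monthly.max(),
                       temperate_climate.t_monthly.mean())
    warmed = temperate_climate.t_monthly + 6.0
    ncgs = []
    for k in (0.0, 0.03, 0.10):
        p = with_overrides(phys, k_nichebreadth=k)
        bal = annual_carbon_balance(plant, warmed,
                                    temperate_climate.p_monthly,
                                    temperate_climate.rsds_monthly,
                                    temperate_climate.lat, 680.0, p)
        ncgs.append(bal.ncg)
    assert ncgs[0] >= ncgs[1] >= ncgs[2]


def test_presets_cover_scenario_grid():
    alphas = {v["alpha"] for v in PRESETS.values()}
    scales = {v["dispersal_scale"] for v in PRESETS.values()}
    assert {0.01, 1.0} <= alphas
    assert {200.0, 1100.0} <= scales


def test_state_snapshot_roundtrip(small_world, tmp_path):
    """Per-cell state snapshots survive a NetCDF round-trip."""
    import xarray as xr
    sim = Simulation(_short_config(), grids=small_world, **FAST)
    state = sim.initialise()
    ds = sim.state_dataset(state, 680.0)
    path = tmp_path / "state.nc"
    ds.to_netcdf(path, engine="scipy")
    with xr.open_dataset(path, engine="scipy") as back:
        back = back.load()
    assert np.allclose(back["height"].values, state.height)
    assert np.array_equal(back["occupied"].values.astype(bool),
                          state.occupied)


def test_run_simulation_metadata(small_world):
    series = run_simulation(_short_config(), grids=small_world, **FAST)
    assert series.attrs["config"]["alpha"] == 1.0
    assert series.attrs["omega_ref"] > 0
    assert {"biomass_PgC", "soil_PgC", "npp_PgC_yr",
            "weathering_molC_yr"} <= set(series.columns)
    assert len(series) == len(np.arange(-20.0, 80.1, 10.0))
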