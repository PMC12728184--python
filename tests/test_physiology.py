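"""Unit and property tests for the annual carbon-balance layer."""

import numpy as np
import pytest
from scipy.optimize import brentq

from treedsim.params import PhysiologyParams, with_overrides
from treedsim.physiology import (CarbonPools, PlantState, absorbed_par,
                                 adt_to_mm_s, allometry, annual_balance_arrays,
                                 annual_carbon_balance, day_length_hours,
                                 equilibrium_evapotranspiration,
                                 heat_frost_damage, leaf_area_index,
                                 light_extinction, maintenance_respiration,
                                 monthly_photosynthesis, net_carbon_gain,
                                 net_primary_productivity, niche_stress,
                                 solve_water_balance, specific_leaf_area,
                                 turnover_costs)

from _reference import (reference_annual_balance,
                        reference_monthly_photosynthesis)
from conftest import random_climate


# ---------------------------------------------------------------------------
# leaf economics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a_ll, expected", [
    (1.0 / 12.0, (2e-4 / 0.47) * 10 ** 2.25),   # one-month leaves
    (2.0, 0.015446),                            # two-year evergreen leaves
])
def test_specific_leaf_area_values(a_ll, expected):
    assert specific_leaf_area(a_ll) == pytest.approx(expected, rel=1e-4)


def test_specific_leaf_area_declines_with_longevity():
    assert specific_leaf_area(4.0) < specific_leaf_area(1.0) \
        < specific_leaf_area(0.25)


def test_specific_leaf_area_rejects_nonpositive():
    with pytest.raises(ValueError):
        specific_leaf_area(0.0)


def test_leaf_area_index_linear():
    assert leaf_area_index(0.0, 0.015, 5.0) == 0.0
    assert leaf_area_index(1000.0, 0.015, 5.0) == pytest.approx(3.0)
    assert leaf_area_index(2000.0, 0.015, 5.0) == pytest.approx(6.0)
    with pytest.raises(ValueError):
        leaf_area_index(1000.0, 0.015, 0.0)


def test_lai_decreasing_in_leaf_longevity(phys):
    """SLA falls with a_ll, so at fixed C_leaf and CA the LAI falls too."""
    lais = [leaf_area_index(5e3, specific_leaf_area(a), 30.0)
            for a in (0.25, 1.0, 4.0, 10.0)]
    assert all(a > b for a, b in zip(lais, lais[1:]))


# ---------------------------------------------------------------------------
# niche stress
# ---------------------------------------------------------------------------

def test_niche_stress_perfect_match_is_one():
    assert niche_stress((0.0, 20.0, 10.0), (0.0, 20.0, 10.0), 0.1) == 1.0


def test_niche_stress_zero_breadth_ignores_deviation():
    assert niche_stress((-30.0, 45.0, 5.0), (0.0, 20.0, 10.0), 0.0) == 1.0


def test_niche_stress_ten_degree_deviation():
    """At 10 degC mean deviation and k = 0.03 productivity drops to ~5%."""
    phi = niche_stress((0.0, 20.0, 20.0), (0.0, 20.0, 10.0), 0.03)
    assert phi == pytest.approx(np.exp(-3.0), rel=1e-12)
    assert phi == pytest.approx(0.0498, abs=2e-4)


def test_niche_stress_takes_strictest_component():
    phi = niche_stress((-5.0, 20.0, 10.0), (0.0, 20.0, 10.0), 0.1)
    assert phi == pytest.approx(np.exp(-0.1 * 25.0))


def test_niche_stress_rejects_negative_k():
    with pytest.raises(ValueError):
        niche_stress((0, 1, 0.5), (0, 1, 0.5), -0.1)


def test_niche_stress_bounded_random():
    rng = np.random.default_rng(7)
    for _ in range(200):
        t = np.sort(rng.uniform(-40, 40, 3))
        v = np.sort(rng.uniform(-40, 40, 3))
        phi = niche_stress((t[0], t[2], t[1]), (v[0], v[2], v[1]),
                           rng.choice([0.0, 0.03, 0.1]))
        assert 0.0 <= phi <= 1.0


# ---------------------------------------------------------------------------
# light capture
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("deciduous, a_ll, expected", [
    (True, 0.5, 0.6), (False, 6.0, 0.4), (False, 2.0, 0.5),
    (True, 2.0, 0.5), (False, 0.5, 0.5),
])
def test_light_extinction_rule(deciduous, a_ll, expected, phys):
    assert light_extinction(deciduous, a_ll, phys) == expected


def test_absorbed_par_vanishes_without_leaves_or_under_full_stress(phys):
    rsds = np.full(12, 200.0)
    zero_lai = absorbed_par(rsds, np.zeros(12), False, 2.0, 1.0, phys)
    assert np.all(zero_lai == 0.0)
    stressed = absorbed_par(rsds, np.full(12, 4.0), False, 2.0, 0.0, phys)
    assert np.all(stressed == 0.0)


def test_absorbed_par_half_of_rsds_is_par(phys):
    rsds = np.full(12, 200.0)
    apar = absorbed_par(rsds, np.full(12, 1e9), False, 2.0, 1.0, phys)
    # saturated canopy absorbs all PAR times the stand scaling factor
    assert np.allclose(apar, 0.5 * 200.0 * phys.alpha_leaf_stand)


# ---------------------------------------------------------------------------
# photosynthesis
# ---------------------------------------------------------------------------

def test_photosynthesis_zero_apar_zero_flux(phys):
    a_gross, a_dt = monthly_photosynthesis(0.0, 25.0, 12.0, 680.0, 0.8, phys)
    assert a_gross == 0.0 and a_dt == 0.0


def test_photosynthesis_nondecreasing_in_apar(phys):
    vals = [monthly_photosynthesis(a, 22.0, 12.0, 680.0, 0.8, phys)[0]
            for a in np.linspace(0, 150, 30)]
    assert all(b >= a for a, b in zip(vals, vals[1:]))


def test_photosynthesis_rejects_bad_lambda(phys):
    with pytest.raises(ValueError):
        monthly_photosynthesis(50.0, 22.0, 12.0, 680.0, 0.0, phys)


def test_photosynthesis_matches_scalar_reference(phys):
    """Double-implementation oracle on random input tuples."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        apar = rng.uniform(0, 120)
        t = rng.uniform(-5, 40)
        dayl = rng.uniform(6, 18)
        pa = rng.uniform(300, 2000)
        lam = rng.uniform(0.1, 0.8)
        h = rng.uniform(0.5, 80)
        got = monthly_photosynthesis(apar, t, dayl, pa, lam, phys, height=h)
        want = reference_monthly_photosynthesis(apar, t, dayl, pa, lam, phys,
                                                height=h)
        assert got[0] == pytest.approx(want[0], rel=1e-10, abs=1e-12)
        assert got[1] == pytest.approx(want[1], rel=1e-10, abs=1e-12)


# ---------------------------------------------------------------------------
# water balance
# ---------------------------------------------------------------------------

def _closure(phys, cpot_mm=2e-4):
    """A_dt(lambda) as a volumetric flux, increasing in lambda."""
    def a_dt(lam):
        fc = max((lam * 680.0 - 45.0) / (lam * 680.0 + 90.0), 0.0)
        return cpot_mm * fc
    return a_dt


def test_water_balance_well_watered_lambda_max(phys):
    lam, gc, aet = solve_water_balance(500.0, 60.0, 680.0, phys.g_min,
                                       _closure(phys), phys)
    assert lam == phys.lambda_max
    assert aet <= 500.0


def test_water_balance_zero_precipitation(phys):
    lam, gc, aet = solve_water_balance(0.0, 60.0, 680.0, phys.g_min,
                                       _closure(phys), phys)
    assert aet == 0.0


def test_water_balance_root_residual(phys):
    """In the water-limited regime the solved lambda closes the balance to
    better than 1e-6 mm."""
    clos = _closure(phys)
    supply = 20.0
    lam, gc, aet = solve_water_balance(supply, 80.0, 680.0, phys.g_min,
                                       clos, phys)
    assert phys.lambda_min < lam < phys.lambda_max
    demand = 80.0 * phys.alpha_m / (1.0 + phys.g_m / gc)
    assert abs(demand - supply) < 1e-6
    assert aet == pytest.approx(supply, abs=1e-6)


def test_water_balance_rejects_negative_supply(phys):
    with pytest.raises(ValueError):
        solve_water_balance(-1.0, 60.0, 680.0, phys.g_min, _closure(phys),
                            phys)


def test_water_conservation_random_cells(phys):
    """AET never exceeds precipitation in any month (closed water balance)."""
    rng = np.random.default_rng(5)
    for _ in range(40):
        c = random_climate(rng)
        plant = PlantState(rng.uniform(1, 50), rng.uniform(100, 3e4),
                           rng.uniform(0.2, 8.0), bool(rng.integers(2)), 1.0,
                           c.t_monthly.min(), c.t_monthly.max(),
                           c.t_monthly.mean())
        bal = annual_carbon_balance(plant, c.t_monthly, c.p_monthly,
                                    c.rsds_monthly, c.lat, 680.0, phys)
        assert np.all(bal.aet_monthly <= c.p_monthly + 1e-9)
        assert np.all((bal.lambda_monthly >= phys.lambda_min - 1e-12)
                      & (bal.lambda_monthly <= phys.lambda_max + 1e-12))


# ---------------------------------------------------------------------------
# respiration / NPP / turnover / NCG
# ---------------------------------------------------------------------------

def _pools(c_leaf=6e3, c_sap=2e5, c_froot=6e3, ca=30.0):
    return CarbonPools(c_leaf, c_sap, 1e5, c_froot, 5e4, ca)


def test_respiration_zero_pools(phys):
    r = maintenance_respiration(CarbonPools(0, 0, 0, 0, 0, 10.0),
                                np.full(12, 15.0), params=phys)
    assert r == (0.0, 0.0, 0.0)


def test_respiration_monotone_in_temperature(phys):
    cold = maintenance_respiration(_pools(), np.full(12, 10.0), params=phys)
    warm = maintenance_respiration(_pools(), np.full(12, 20.0), params=phys)
    assert all(w > c for w, c in zip(warm, cold))


def test_fineroot_respiration_proportional_to_pool(phys):
    r1 = maintenance_respiration(_pools(c_froot=5e3), np.full(12, 15.0),
                                 params=phys)[2]
    r2 = maintenance_respiration(_pools(c_froot=1e4), np.full(12, 15.0),
                                 params=phys)[2]
    assert r2 == pytest.approx(2.0 * r1)


def test_npp_equation():
    assert net_primary_productivity(1000.0, 200.0, 100.0, 100.0, 0.25) \
        == pytest.approx(450.0)
    assert net_primary_productivity(400.0, 200.0, 100.0, 100.0, 0.25) == 0.0
    assert net_primary_productivity(1000.0, 300.0, 100.0, 100.0, 0.25) \
        < net_primary_productivity(1000.0, 200.0, 100.0, 100.0, 0.25)


def test_turnover_leaf_cases(phys):
    pools = _pools()
    tau = turnover_costs(pools, 2.0, True, 0.0, 0.0, phys)
    assert tau[0] == pytest.approx(pools.c_leaf)        # deciduous: full pool
    tau = turnover_costs(pools, 2.0, False, 0.0, 0.0, phys)
    assert tau[0] == pytest.approx(pools.c_leaf / 2.0)  # evergreen: /a_ll


def test_turnover_damage_caps_at_doubling(phys):
    pools = _pools()
    base = turnover_costs(pools, 2.0, False, 0.0, 0.0, phys)
    huge = turnover_costs(pools, 2.0, False, 0.9, 0.9, phys)
    assert huge[1] == pytest.approx(2.0 * base[1])      # never more than x2
    assert huge[2] == pytest.approx(2.0 * base[2])


def test_fineroot_turnover_cases(phys):
    pools = _pools(c_froot=4e3)
    assert turnover_costs(pools, 2.0, False, 0, 0, phys)[4] \
        == pytest.approx(2e3)                           # a_ll > 1: /a_ll
    assert turnover_costs(pools, 0.5, False, 0, 0, phys)[4] \
        == pytest.approx(4e3)                           # a_ll <= 1: full pool


def test_net_carbon_gain():
    assert net_carbon_gain(500.0, (100.0,) * 5, 1.0) == 0.0
    assert net_carbon_gain(500.0, (200.0, 100.0, 100.0, 100.0, 100.0), 2.0) \
        == pytest.approx(200.0)
    with pytest.raises(ValueError):
        net_carbon_gain(500.0, (0.0,) * 5, 0.0)


def test_heat_frost_damage_contract(phys):
    assert heat_frost_damage(np.full(12, 20.0), phys) == (0.0, 0.0)
    hd, fd = heat_frost_damage(np.full(12, 70.0), phys)
    assert hd == pytest.approx(1.0) and fd == 0.0       # saturated heat
    hd1, _ = heat_frost_damage(np.full(12, 36.0), phys)
    hd2, _ = heat_frost_damage(np.full(12, 39.0), phys)
    assert hd2 > hd1 >= 0.0
    hd, fd = heat_frost_damage(np.r_[np.full(6, 60.0), np.full(6, -60.0)],
                               phys)
    assert hd + fd <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def test_allometry_monotone_in_height(phys):
    p1 = allometry(10.0, 5e3, 1.0, phys)
    p2 = allometry(20.0, 5e3, 1.0, phys)
    assert p2.crown_area > p1.crown_area
    assert p2.c_sapwood > p1.c_sapwood
    assert p2.c_heartwood > p1.c_heartwood


def test_allometry_fineroot_ratio(phys):
    pools = allometry(10.0, 5e3, 1.7, phys)
    assert pools.c_fineroot == pytest.approx(1.7 * 5e3)


def test_allometry_zero_leaf(phys):
    pools = allometry(10.0, 0.0, 1.0, phys)
    assert pools.c_heartwood == 0.0 and pools.c_fineroot == 0.0
    assert pools.crown_area >= phys.ca_min


def test_allometry_golden_values(phys):
    """Frozen fixture: pools at the documented default constants."""
    pools = allometry(30.0, 9600.0, 1.0, phys, a_ll=2.0)
    leaf_area = 9600.0 * specific_leaf_area(2.0)
    assert pools.crown_area == pytest.approx(
        0.013 * 9600.0 ** 0.75 * 30.0 ** 0.25 + 0.1 * 30.0, rel=1e-12)
    assert pools.c_sapwood == pytest.approx(
        55.0 * leaf_area * 30.0 + 50.0 * pools.crown_area * 30.0, rel=1e-12)
    assert pools.c_heartwood == pytest.approx(2.2 * leaf_area * 900.0,
                                              rel=1e-12)
    assert pools.c_coarseroot == pytest.approx(
        0.25 * (pools.c_sapwood + pools.c_heartwood), rel=1e-12)


# ---------------------------------------------------------------------------
# full pipeline oracle
# ---------------------------------------------------------------------------

def test_annual_balance_matches_scalar_reference(phys):
    """The vectorised pipeline equals an independently coded scalar
    implementation of the same documented formulas (50 random cells)."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        c = random_climate(rng)
        h = rng.uniform(0.6, 70.0)
        c_leaf = 10 ** rng.uniform(1.5, 4.5)
        a_ll = 10 ** rng.uniform(np.log10(1 / 12), 1.0)
        dec = bool(rng.integers(2))
        niche = (c.t_monthly.min() + rng.normal(0, 3),
                 c.t_monthly.max() + rng.normal(0, 3),
                 c.t_monthly.mean() + rng.normal(0, 3))
        niche = (min(niche), max(niche), sorted(niche)[1])
        p_a = rng.uniform(400, 1800)
        got = annual_balance_arrays(h, c_leaf, a_ll, dec, 1.0, *niche,
                                    c.t_monthly, c.p_monthly, c.rsds_monthly,
                                    c.lat, p_a, phys, lam_iters=70)
        want = reference_annual_balance(h, c_leaf, a_ll, dec, 1.0, niche,
                                        list(c.t_monthly), list(c.p_monthly),
                                        list(c.rsds_monthly), c.lat, p_a,
                                        phys)
        for key in ("gpp", "npp", "ncg", "r_leaf", "r_sapwood", "r_fineroot",
                    "tau_leaf", "tau_sapwood", "tau_fineroot"):
            assert float(got[key]) == pytest.approx(want[key], rel=1e-8,
                                                    abs=1e-8), key


def test_fertilisation_off_never_raises_gpp(phys):
    """Clamping CO2 to the reference level can only lower carbon gain at
    elevated CO2."""
    rng = np.random.default_rng(3)
    fert_on = phys
    fert_off = with_overrides(phys, co2_fertilisation=False)
    for _ in range(25):
        c = random_climate(rng)
        plant = PlantState(rng.uniform(2, 40), rng.uniform(500, 2e4),
                           rng.uniform(0.3, 6.0), False, 1.0,
                           c.t_monthly.min(), c.t_monthly.max(),
                           c.t_monthly.mean())
        on = annual_carbon_balance(plant, c.t_monthly, c.p_monthly,
                                   c.rsds_monthly, c.lat, 1590.0, fert_on)
        off = annual_carbon_balance(plant, c.t_monthly, c.p_monthly,
                                    c.rsds_monthly, c.lat, 1590.0, fert_off)
        assert off.gpp <= on.gpp + 1e-9
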