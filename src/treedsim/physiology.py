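"""Annual carbon balance of a reference plant.

For one plant (six key traits) in one grid cell and one year of monthly
climate, this module computes the full chain

    SLA -> LAI -> niche-stressed APAR -> photosynthesis under a closed
    water balance -> maintenance/growth respiration -> NPP -> tissue
    turnover costs -> net carbon gain (NCG),

the model's fitness measure.  Two surfaces are exposed: scalar functions
for each physiological step, and :func:`annual_balance_arrays`, a fully
vectorised implementation over arbitrary batches of (plant, climate)
pairs, which the trait optimiser and the grid engine rely on.

Units: temperatures degC, precipitation mm month-1, shortwave radiation
W m-2, carbon fluxes g C m-2 (crown) yr-1, pools g C per plant, CO2 as
ppm (converted to mole fraction internally).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import PhysiologyParams

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 365.25 / 12.0
SECONDS_PER_HOUR = 3600.0
MOLAR_MASS_C = 12.011          # g mol-1
MOLAR_VOLUME_MM = 22.414       # mm3 CO2 per mm2 per (mol m-2) -> mm per mol m-2
WM2_TO_MJ_DAY = 0.0864         # W m-2 -> MJ m-2 day-1
LATENT_HEAT_MJ = 2.45          # MJ kg-1 of water
PSYCHROMETRIC = 0.0665         # kPa K-1

__all__ = [
    "PlantState",
    "CarbonPools",
    "CarbonBalance",
    "specific_leaf_area",
    "leaf_area_index",
    "niche_stress",
    "light_extinction",
    "absorbed_par",
    "monthly_photosynthesis",
    "solve_water_balance",
    "maintenance_respiration",
    "net_primary_productivity",
    "turnover_costs",
    "net_carbon_gain",
    "heat_frost_damage",
    "hydraulic_limitation",
    "stand_light_capture",
    "allometry",
    "day_length_hours",
    "equilibrium_evapotranspiration",
    "annual_balance_arrays",
    "annual_carbon_balance",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PlantState:
    """The per-cell reference plant: six key traits plus its climatic niche."""

    height: float                  # H, m
    c_leaf: float                  # g C per plant
    a_ll: float                    # leaf longevity, yr
    deciduous: bool                # phenology: True deciduous, False evergreen
    root_shoot: float              # fine-root : leaf carbon ratio
    t_min_veg: float               # niche coldest-month temperature, degC
    t_max_veg: float               # niche warmest-month temperature, degC
    t_mean_veg: float              # niche mean annual temperature, degC

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("plant height must be positive")
        if self.c_leaf < 0:
            raise ValueError("leaf carbon pool must be non-negative")
        if not (self.t_min_veg <= self.t_mean_veg <= self.t_max_veg):
            raise ValueError("niche temperatures must be ordered min <= mean <= max")

    @property
    def phenology(self) -> int:
        """0 = deciduous, 1 = evergreen."""
        return 0 if self.deciduous else 1


@dataclass
class CarbonPools:
    """Per-plant carbon pools and crown area from the allometric rules."""

    c_leaf: float
    c_sapwood: float
    c_heartwood: float
    c_fineroot: float
    c_coarseroot: float
    crown_area: float

    @property
    def total(self) -> float:
        return (self.c_leaf + self.c_sapwood + self.c_heartwood
                + self.c_fineroot + self.c_coarseroot)


@dataclass
class CarbonBalance:
    """Annual fluxes of one plant in one cell (g C m-2 yr-1 unless noted)."""

    gpp: float
    r_leaf: float
    r_sapwood: float
    r_fineroot: float
    npp: float
    tau_leaf: float                # g C plant-1 yr-1
    tau_sapwood: float
    tau_heartwood: float
    tau_coarseroot: float
    tau_fineroot: float
    ncg: float
    aet_monthly: np.ndarray        # mm month-1, length 12
    lambda_monthly: np.ndarray     # ci:ca ratio, length 12
    phi: float                     # niche stress factor in [0, 1]
    pools: CarbonPools


# ---------------------------------------------------------------------------
# leaf economics and light capture
# ---------------------------------------------------------------------------

def specific_leaf_area(a_ll, dm_c: float = 0.47):
    """Specific leaf area (m2 per g C) from leaf longevity (yr).

    The leaf-economics trade-off: short-lived leaves are cheap per area,
    long-lived leaves are dense.  Base-10 logarithm of leaf longevity in
    months.
    """
    a_ll = np.asarray(a_ll, dtype=float)
    if np.any(a_ll <= 0):
        raise ValueError("leaf longevity must be positive")
    out = (2.0e-4 / dm_c) * 10.0 ** (2.25 - 0.5 * np.log10(a_ll * 12.0))
    return out if out.ndim else float(out)


def leaf_area_index(c_leaf, sla, crown_area):
    """LAI = C_leaf * SLA / CA (dimensionless)."""
    crown_area = np.asarray(crown_area, dtype=float)
    if np.any(crown_area <= 0):
        raise ValueError("crown area must be positive")
    out = np.asarray(c_leaf, dtype=float) * np.asarray(sla, dtype=float) / crown_area
    return out if out.ndim else float(out)


def niche_stress(t_local, niche, k_nichebreadth):
    """Gaussian climatic-niche penalty Phi in [0, 1].

    ``t_local`` and ``niche`` are (coldest-month, warmest-month, annual-mean)
    temperature triples; each deviation is penalised as exp(-k * delta^2) and
    the strictest of the three applies.
    """
    if np.any(np.asarray(k_nichebreadth) < 0):
        raise ValueError("niche breadth parameter must be non-negative")
    t_min_l, t_max_l, t_mean_l = (np.asarray(v, dtype=float) for v in t_local)
    t_min_v, t_max_v, t_mean_v = (np.asarray(v, dtype=float) for v in niche)
    phi_cold = np.exp(-k_nichebreadth * (t_min_l - t_min_v) ** 2)
    phi_heat = np.exp(-k_nichebreadth * (t_max_l - t_max_v) ** 2)
    phi_mean = np.exp(-k_nichebreadth * (t_mean_l - t_mean_v) ** 2)
    out = np.minimum(np.minimum(phi_heat, phi_cold), phi_mean)
    return out if out.ndim else float(out)


def light_extinction(deciduous, a_ll, params: PhysiologyParams):
    """Light extinction coefficient: 0.6 for deciduous plants with a_ll < 1,
    0.4 for plants with a_ll > 4, and 0.5 in all other cases."""
    deciduous = np.asarray(deciduous, dtype=bool)
    a_ll = np.asarray(a_ll, dtype=float)
    out = np.full(np.broadcast(deciduous, a_ll).shape, params.k_ext_default)
    out = np.where(a_ll > 4.0, params.k_ext_longleaf, out)
    out = np.where(deciduous & (a_ll < 1.0), params.k_ext_deciduous, out)
    return out if out.ndim else float(out)


def absorbed_par(rsds_monthly, lai_monthly, deciduous, a_ll, phi,
                 params: PhysiologyParams):
    """Monthly absorbed PAR (W m-2): PAR = 0.5 RSDS, Beer-Lambert canopy
    absorption, leaf-to-stand scaling and the niche-stress penalty.

    ``lai_monthly`` already carries the deciduous growing-season mask (LAI
    is zero in leaf-off months), so out-of-season APAR vanishes.
    """
    k = np.asarray(light_extinction(deciduous, a_ll, params))[..., None]
    par = 0.5 * np.asarray(rsds_monthly, dtype=float)
    phi = np.asarray(phi, dtype=float)[..., None]
    return par * (1.0 - np.exp(-k * np.asarray(lai_monthly, dtype=float))) \
        * params.alpha_leaf_stand * phi


# ---------------------------------------------------------------------------
# solar geometry and equilibrium evapotranspiration
# ---------------------------------------------------------------------------

_MID_MONTH_DOY = np.arange(12) * DAYS_PER_MONTH + DAYS_PER_MONTH / 2.0


def day_length_hours(lat, month_doy=None):
    """Daylight hours per month from latitude and mid-month solar declination."""
    doy = _MID_MONTH_DOY if month_doy is None else np.asarray(month_doy, dtype=float)
    lat_r = np.deg2rad(np.asarray(lat, dtype=float))[..., None]
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25))
    cos_h0 = np.clip(-np.tan(lat_r) * np.tan(decl), -1.0, 1.0)
    return 24.0 / np.pi * np.arccos(cos_h0)


def equilibrium_evapotranspiration(t_monthly, rsds_monthly,
                                   params: PhysiologyParams):
    """Priestley-Taylor equilibrium evapotranspiration, mm day-1."""
    t = np.asarray(t_monthly, dtype=float)
    es_slope = (4098.0 * 0.6108 * np.exp(17.27 * t / (t + 237.3))
                / (t + 237.3) ** 2)                      # kPa K-1
    rn = params.net_sw_fraction * np.maximum(np.asarray(rsds_monthly, float), 0.0)
    rn_mj = rn * WM2_TO_MJ_DAY
    return es_slope / (es_slope + PSYCHROMETRIC) * rn_mj / LATENT_HEAT_MJ


# ---------------------------------------------------------------------------
# photosynthesis
# ---------------------------------------------------------------------------

def _temperature_inhibition(t, params: PhysiologyParams):
    """Trapezoidal temperature factor of C3 assimilation in [0, 1]."""
    up = (t - params.t_photo_min) / (params.t_photo_opt_lo - params.t_photo_min)
    down = (params.t_photo_max - t) / (params.t_photo_max - params.t_photo_opt_hi)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


def hydraulic_limitation(height, params: PhysiologyParams):
    """Hydraulic height limitation of assimilation: 1/(1 + (H/h_hyd)^2).

    Water transport resistance grows with path length, closing stomata
    earlier in tall canopies; this is what ultimately bounds sustainable
    height together with the woody turnover burden.
    """
    h = np.asarray(height, dtype=float)
    return 1.0 / (1.0 + (h / params.h_hydraulic) ** 2)


def stand_light_capture(height, params: PhysiologyParams):
    """Stature-dependent stand-level light capture in (0, 1].

    Short stands lose part of the incident light to sub-canopy levels and
    neighbouring vegetation; the deficit decays exponentially with
    height, so growing tall pays off in light capture as well as in
    direct competition.
    """
    h = np.asarray(height, dtype=float)
    return 1.0 - params.understory_loss * np.exp(-h / params.h_understory)


def _gamma_star(t, params: PhysiologyParams):
    """CO2 compensation point (ppm) with a Q10 temperature response."""
    return params.gamma_star25 * params.q10_gamma_star ** ((t - 25.0) / 10.0)


def _co2_factor(ci_ppm, gamma, clip=True):
    fc = (ci_ppm - gamma) / (ci_ppm + 2.0 * gamma)
    return np.maximum(fc, 0.0) if clip else fc


def _effective_ca(p_a_ppm, params: PhysiologyParams):
    """Ambient CO2 seen by the photosynthesis terms.

    With CO2 fertilisation switched off the assimilation chemistry is
    clamped to the reference concentration; everything else is untouched.
    """
    if params.co2_fertilisation:
        return p_a_ppm
    return params.co2_ref_ppm


def monthly_photosynthesis(apar, t_month, day_length, p_a, lam,
                           params: PhysiologyParams | None = None,
                           r_leaf_day=0.0, height=None):
    """Gross photosynthesis for one month of mean conditions.

    A light-use-efficiency formulation: gross assimilation is the minimum
    of a light-limited rate (proportional to APAR) and a Rubisco-limited
    capacity cap, both scaled by a trapezoidal temperature-inhibition
    factor and the CO2 dependence (ci - gamma*)/(ci + 2 gamma*) with
    ci = lambda * ca.

    Parameters
    ----------
    apar : W m-2 absorbed PAR (monthly mean over 24 h).
    t_month : degC.
    day_length : daylight hours (for the daytime-flux conversion only).
    p_a : ambient CO2, ppm.
    lam : ci:ca ratio in (0, lambda_max].
    r_leaf_day : daily leaf maintenance respiration, g C m-2 day-1.

    Returns
    -------
    (a_gross, a_dt) : gross assimilation in g C m-2 month-1 and net
    daytime assimilation in g C m-2 day-1 (floored at zero), the latter
    driving canopy conductance in the water balance.
    """
    params = params or PhysiologyParams()
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda (ci:ca) must be positive")
    apar = np.asarray(apar, dtype=float)
    if np.any(apar < 0):
        raise ValueError("APAR must be non-negative")
    ca = _effective_ca(np.asarray(p_a, dtype=float), params)
    gamma = _gamma_star(np.asarray(t_month, dtype=float), params)
    fc = _co2_factor(lam_arr * ca, gamma)
    f_t = _temperature_inhibition(np.asarray(t_month, dtype=float), params)
    f_hyd = 1.0 if height is None else (hydraulic_limitation(height, params)
                                        * stand_light_capture(height, params))
    apar_mj = apar * WM2_TO_MJ_DAY
    a_daily = (params.lue_max * f_t * f_hyd * fc
               * np.minimum(apar_mj, params.apar_sat_mj))
    a_gross = a_daily * DAYS_PER_MONTH
    a_dt = np.maximum(a_daily - np.asarray(r_leaf_day, dtype=float), 0.0)
    if np.ndim(a_gross) == 0:
        return float(a_gross), float(a_dt)
    return a_gross, a_dt


# ---------------------------------------------------------------------------
# water balance
# ---------------------------------------------------------------------------

def _gc_from_adt(a_dt_mm_s, lam, ca_frac, g_min):
    """Canopy conductance (mm s-1) from net daytime assimilation."""
    return 1.6 * a_dt_mm_s / (ca_frac * (1.0 - lam)) + g_min


def adt_to_mm_s(a_dt_gc_day, day_length):
    """g C m-2 day-1 of daytime CO2 uptake -> volumetric flux in mm s-1."""
    dayl_s = np.maximum(np.asarray(day_length, dtype=float), 1e-3) * SECONDS_PER_HOUR
    return np.asarray(a_dt_gc_day, dtype=float) / MOLAR_MASS_C / dayl_s * MOLAR_VOLUME_MM


def solve_water_balance(precip_month, e_eq, p_a, g_min, a_dt_fn,
                        params: PhysiologyParams | None = None):
    """Close the monthly water balance AET = min(E_supply, E_demand).

    ``a_dt_fn(lam)`` must return net daytime assimilation as a volumetric
    flux (mm s-1); canopy conductance follows g_c = 1.6 A_dt/(ca (1-lam))
    + g_min and atmospheric demand E_demand = E_eq alpha_m/(1 + g_m/g_c).
    If supply covers the demand at lambda_max, lambda = lambda_max;
    otherwise lambda is the bracketed root of E_demand(lam) = E_supply
    (residual < 1e-6 mm).  If even the lower lambda bound over-demands,
    lambda is pinned there and AET equals the supply.

    Returns (lambda, g_c mm s-1, AET in the units of ``precip_month``).
    """
    params = params or PhysiologyParams()
    if precip_month < 0 or e_eq < 0:
        raise ValueError("precipitation and equilibrium evaporation must be >= 0")
    ca_frac = _effective_ca(p_a, params) * 1e-6

    def demand(lam):
        gc = _gc_from_adt(a_dt_fn(lam), lam, ca_frac, g_min)
        return e_eq * params.alpha_m / (1.0 + params.g_m / gc)

    lam_hi, lam_lo = params.lambda_max, params.lambda_min
    d_hi = demand(lam_hi)
    if precip_month >= d_hi:
        lam = lam_hi
        dem = d_hi
    else:
        d_lo = demand(lam_lo)
        if precip_month <= d_lo:
            logger.warning(
                "water balance has no bracketing root (supply %.3g < minimum "
                "demand %.3g); pinning lambda at its lower bound", precip_month, d_lo)
            lam, dem = lam_lo, d_lo
        else:
            lam = brentq(lambda x: demand(x) - precip_month, lam_lo, lam_hi,
                         xtol=1e-12, rtol=8.9e-16)
            dem = demand(lam)
    gc = _gc_from_adt(a_dt_fn(lam), lam, ca_frac, g_min)
    return float(lam), float(gc), float(min(precip_month, dem))


# ---------------------------------------------------------------------------
# respiration, NPP, turnover, NCG
# ---------------------------------------------------------------------------

def respiration_temperature_factor(t, params: PhysiologyParams):
    """Modified-Arrhenius (Lloyd-Taylor) temperature response, ~1 at 10 degC."""
    t = np.asarray(t, dtype=float)
    return np.exp(params.resp_e0 * (1.0 / params.resp_t1
                                    - 1.0 / (t + params.resp_t2)))


def maintenance_respiration(pools: CarbonPools, t_monthly, deciduous=False,
                            params: PhysiologyParams | None = None,
                            grow_mask=None, a_ll: float = 2.0):
    """Annual leaf/sapwood/fine-root maintenance respiration, g C m-2 yr-1.

    Sapwood and fine-root terms are proportional to the tissue nitrogen
    pool (carbon over the tissue C:N ratio, per crown area); the leaf
    term is proportional to leaf *area* (a Rubisco-capacity proxy: leaf
    nitrogen per area varies little along the leaf economics spectrum).
    All terms carry the Lloyd-Taylor temperature factor, accumulated
    monthly.  Deciduous leaves respire only in growing-season months.
    """
    params = params or PhysiologyParams()
    t = np.asarray(t_monthly, dtype=float)
    g = respiration_temperature_factor(t, params)
    if grow_mask is None:
        grow_mask = (t > params.t_grow) if deciduous else np.ones_like(t, dtype=bool)
    ca = pools.crown_area
    lai = pools.c_leaf * specific_leaf_area(a_ll, params.dm_c) / ca
    n_sap = pools.c_sapwood / params.cn_sapwood / ca
    n_root = pools.c_fineroot / params.cn_fineroot / ca
    r_leaf = params.k_resp_leaf * lai * np.sum(g * grow_mask) / 12.0
    r_sap = params.k_resp_sapwood * n_sap * np.sum(g) / 12.0
    r_root = params.k_resp_fineroot * n_root * np.sum(g) / 12.0
    return float(r_leaf), float(r_sap), float(r_root)


def net_primary_productivity(gpp, r_leaf, r_sapwood, r_fineroot, r_gr):
    """NPP = (1 - r_gr) (GPP - R_leaf - R_sapwood - R_fineroot); may be < 0."""
    return (1.0 - r_gr) * (gpp - r_leaf - r_sapwood - r_fineroot)


def heat_frost_damage(t_monthly, params: PhysiologyParams | None = None):
    """Heat/frost damage indices (HD, FD) raising woody turnover costs.

    Linear degree-month indices above/below the heat and frost thresholds,
    jointly capped at HD + FD <= 1 so the turnover factor (1 + HD + FD)
    never exceeds 2.
    """
    params = params or PhysiologyParams()
    t = np.asarray(t_monthly, dtype=float)
    hd = np.mean(np.maximum(t - params.hd_threshold, 0.0), axis=-1) / params.hd_scale
    fd = np.mean(np.maximum(params.fd_threshold - t, 0.0), axis=-1) / params.fd_scale
    total = hd + fd
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    hd, fd = hd * scale, fd * scale
    if np.ndim(hd) == 0:
        return float(hd), float(fd)
    return hd, fd


def turnover_costs(pools: CarbonPools, a_ll, deciduous, hd, fd,
                   params: PhysiologyParams | None = None):
    """Annual turnover carbon costs per plant (g C plant-1 yr-1).

    Woody pools turn over at fixed rates scaled by (1 + HD + FD), capped
    at doubling.  Leaves cost C_leaf/a_ll per year if evergreen and the
    full C_leaf if deciduous; fine roots mirror the leaves for a_ll > 1.
    """
    params = params or PhysiologyParams()
    if hd < 0 or fd < 0:
        raise ValueError("damage indices must be non-negative")
    damage = min(1.0 + hd + fd, 2.0)
    tau_sap = pools.c_sapwood * params.f_sapwood * damage
    tau_heart = pools.c_heartwood * params.f_heartwood * damage
    tau_croot = pools.c_coarseroot * params.f_coarseroot * damage
    tau_leaf = pools.c_leaf * (1.0 if deciduous else 1.0 / a_ll)
    tau_froot = pools.c_fineroot * (1.0 / a_ll if a_ll > 1.0 else 1.0)
    return (float(tau_leaf), float(tau_sap), float(tau_heart),
            float(tau_croot), float(tau_froot))


def net_carbon_gain(npp, taus, crown_area):
    """NCG = NPP - sum(turnover costs)/CA, g C m-2 yr-1."""
    if crown_area <= 0:
        raise ValueError("crown area must be positive")
    return npp - sum(taus) / crown_area


# ---------------------------------------------------------------------------
# allometry
# ---------------------------------------------------------------------------

def allometry(height, c_leaf, root_shoot, params: PhysiologyParams | None = None,
              a_ll: float = 2.0):
    """Derive the full carbon-pool set and crown area from (H, C_leaf, r:s).

    Crown area grows with both leaf carbon and height (a tall plant
    necessarily occupies a wide crown); sapwood follows the pipe model
    (proportional to leaf *area* times height, so the conducting tissue
    tracks the transpiring surface) plus a structural term proportional
    to crown volume; heartwood accumulates quadratically with height;
    coarse roots mirror a fixed fraction of the stem.  ``a_ll`` sets the
    SLA used to convert leaf carbon to leaf area.
    """
    params = params or PhysiologyParams()
    h = np.asarray(height, dtype=float)
    cl = np.asarray(c_leaf, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be positive")
    if np.any(cl < 0):
        raise ValueError("leaf carbon must be non-negative")
    leaf_area = cl * specific_leaf_area(a_ll, params.dm_c)
    ca = np.maximum(params.k_ca * cl ** params.exp_ca_leaf
                    * h ** params.exp_ca_height + params.k_ca_h * h,
                    params.ca_min)
    c_sap = params.k_sapwood * leaf_area * h + params.k_struct * ca * h
    c_heart = params.k_heartwood * leaf_area * h ** 2
    c_croot = params.k_coarseroot * (c_sap + c_heart)
    c_froot = np.asarray(root_shoot, dtype=float) * cl
    if np.ndim(ca) == 0:
        return CarbonPools(float(cl), float(c_sap), float(c_heart),
                           float(c_froot), float(c_croot), float(ca))
    return CarbonPools(cl, c_sap, c_heart, c_froot, c_croot, ca)


# ---------------------------------------------------------------------------
# vectorised annual balance
# ---------------------------------------------------------------------------

def annual_balance_arrays(height, c_leaf, a_ll, deciduous, root_shoot,
                          niche_tmin, niche_tmax, niche_tmean,
                          t_monthly, p_monthly, rsds_monthly, lat,
                          p_a_ppm, params: PhysiologyParams,
                          lam_iters: int = 60):
    """Vectorised annual carbon balance over broadcastable plant/climate arrays.

    Plant arrays have any common shape S; monthly climate arrays broadcast
    against S + (12,).  The monthly ci:ca ratio is solved by bisection
    (``lam_iters`` halvings of [lambda_min, lambda_max], i.e. to machine
    precision at the default).  Returns a dict of arrays (shape S, or
    S + (12,) for monthly series).
    """
    h = np.asarray(height, dtype=float)
    cl = np.asarray(c_leaf, dtype=float)
    al = np.asarray(a_ll, dtype=float)
    dec = np.asarray(deciduous, dtype=bool)
    rs = np.asarray(root_shoot, dtype=float)
    t_m = np.asarray(t_monthly, dtype=float)
    p_m = np.asarray(p_monthly, dtype=float)
    r_m = np.asarray(rsds_monthly, dtype=float)

    # allometry and leaf economics
    sla = (2.0e-4 / params.dm_c) * 10.0 ** (2.25 - 0.5 * np.log10(al * 12.0))
    ca = np.maximum(params.k_ca * cl ** params.exp_ca_leaf
                    * h ** params.exp_ca_height + params.k_ca_h * h,
                    params.ca_min)
    leaf_area = cl * sla
    c_sap = params.k_sapwood * leaf_area * h + params.k_struct * ca * h
    c_heart = params.k_heartwood * leaf_area * h ** 2
    c_croot = params.k_coarseroot * (c_sap + c_heart)
    c_froot = rs * cl
    lai = leaf_area / ca

    # growing season: deciduous plants carry leaves only in warm months
    grow = np.where(dec[..., None], t_m > params.t_grow, True)
    lai_m = lai[..., None] * grow

    # local climate summary and niche stress
    t_min_loc = t_m.min(axis=-1)
    t_max_loc = t_m.max(axis=-1)
    t_mean_loc = t_m.mean(axis=-1)
    phi = niche_stress(
        (t_min_loc, t_max_loc, t_mean_loc),
        (np.asarray(niche_tmin, float), np.asarray(niche_tmax, float),
         np.asarray(niche_tmean, float)),
        params.k_nichebreadth)
    phi = np.asarray(phi, dtype=float)

    # light capture
    k_ext = np.asarray(light_extinction(dec, al, params))
    apar = (0.5 * r_m * (1.0 - np.exp(-k_ext[..., None] * lai_m))
            * params.alpha_leaf_stand * phi[..., None])
    apar_mj = apar * WM2_TO_MJ_DAY

    # photosynthesis pieces independent of lambda
    ca_ppm = _effective_ca(np.asarray(p_a_ppm, dtype=float), params)
    gamma = _gamma_star(t_m, params)
    f_t = _temperature_inhibition(t_m, params)
    f_height = (hydraulic_limitation(h, params)
                * stand_light_capture(h, params))[..., None]
    cpot = (params.lue_max * f_t * f_height
            * np.minimum(apar_mj, params.apar_sat_mj))

    # monthly leaf respiration (needed inside the conductance closure);
    # area-based: proportional to LAI, a Rubisco-capacity proxy
    g_resp = respiration_temperature_factor(t_m, params)
    r_leaf_m = params.k_resp_leaf * lai[..., None] * g_resp * grow / 12.0
    rl_day = r_leaf_m / DAYS_PER_MONTH

    # water balance: solve ci:ca per month by vectorised bisection
    dayl = day_length_hours(np.asarray(lat, dtype=float))
    k_conv = MOLAR_VOLUME_MM / (MOLAR_MASS_C
                                * np.maximum(dayl, 1e-3) * SECONDS_PER_HOUR)
    ca_frac = ca_ppm * 1e-6
    supply = p_m / DAYS_PER_MONTH                      # mm day-1
    e_eq = equilibrium_evapotranspiration(t_m, r_m, params)
    ea = e_eq * params.alpha_m

    def demand(lam):
        fc = np.maximum((lam * ca_ppm - gamma) / (lam * ca_ppm + 2.0 * gamma), 0.0)
        a_dt = np.maximum(cpot * fc - rl_day, 0.0) * k_conv
        gc = 1.6 * a_dt / (ca_frac * (1.0 - lam)) + params.g_min
        return ea / (1.0 + params.g_m / gc)

    lam_hi = np.full(supply.shape, params.lambda_max)
    d_max = demand(params.lambda_max)
    limited = supply < d_max
    lo = np.full(supply.shape, params.lambda_min)
    hi = np.full(supply.shape, params.lambda_max)
    for _ in range(lam_iters):
        mid = 0.5 * (lo + hi)
        over = demand(mid) > supply
        hi = np.where(over, mid, hi)
        lo = np.where(over, lo, mid)
    lam_sol = 0.5 * (lo + hi)
    lam = np.where(limited, lam_sol, lam_hi)
    dem = demand(lam)
    aet = np.minimum(supply, dem) * DAYS_PER_MONTH     # mm month-1

    # realised assimilation with the closed water balance
    fc = np.maximum((lam * ca_ppm - gamma) / (lam * ca_ppm + 2.0 * gamma), 0.0)
    a_daily = cpot * fc
    gpp_m = a_daily * DAYS_PER_MONTH
    gpp = gpp_m.sum(axis=-1)

    # respiration (sapwood/fine roots year-round, leaves in season)
    r_leaf = r_leaf_m.sum(axis=-1)
    n_sap = c_sap / params.cn_sapwood / ca
    n_root = c_froot / params.cn_fineroot / ca
    g_year = g_resp.mean(axis=-1)
    r_sap = params.k_resp_sapwood * n_sap * g_year
    r_root = params.k_resp_fineroot * n_root * g_year
    npp = (1.0 - params.r_gr) * (gpp - r_leaf - r_sap - r_root)

    # turnover
    hd, fd = heat_frost_damage(t_m, params)
    damage = np.minimum(1.0 + np.asarray(hd) + np.asarray(fd), 2.0)
    tau_sap = c_sap * params.f_sapwood * damage
    tau_heart = c_heart * params.f_heartwood * damage
    tau_croot = c_croot * params.f_coarseroot * damage
    tau_leaf = cl * np.where(dec, 1.0, 1.0 / al)
    tau_froot = c_froot * np.where(al > 1.0, 1.0 / al, 1.0)
    ncg = npp - (tau_leaf + tau_sap + tau_heart + tau_croot + tau_froot) / ca

    return {
        "sla": sla, "crown_area": ca, "lai": lai, "phi": phi,
        "c_sapwood": c_sap, "c_heartwood": c_heart,
        "c_coarseroot": c_croot, "c_fineroot": c_froot,
        "gpp": gpp, "r_leaf": r_leaf, "r_sapwood": r_sap, "r_fineroot": r_root,
        "npp": npp, "hd": np.asarray(hd), "fd": np.asarray(fd),
        "tau_leaf": tau_leaf, "tau_sapwood": tau_sap, "tau_heartwood": tau_heart,
        "tau_coarseroot": tau_croot, "tau_fineroot": tau_froot,
        "ncg": ncg, "aet_monthly": aet, "lambda_monthly": lam,
        "aet_annual": aet.sum(axis=-1),
    }


def annual_carbon_balance(plant: PlantState, t_monthly, p_monthly,
                          rsds_monthly, lat, p_a_ppm,
                          params: PhysiologyParams | None = None,
                          lam_iters: int = 60) -> CarbonBalance:
    """Scalar convenience wrapper: full annual balance for one plant/cell."""
    params = params or PhysiologyParams()
    out = annual_balance_arrays(
        plant.height, plant.c_leaf, plant.a_ll, plant.deciduous,
        plant.root_shoot, plant.t_min_veg, plant.t_max_veg, plant.t_mean_veg,
        np.asarray(t_monthly, float), np.asarray(p_monthly, float),
        np.asarray(rsds_monthly, float), lat, p_a_ppm, params, lam_iters)
    pools = CarbonPools(
        plant.c_leaf, float(out["c_sapwood"]), float(out["c_heartwood"]),
        float(out["c_fineroot"]), float(out["c_coarseroot"]),
        float(out["crown_area"]))
    return CarbonBalance(
        gpp=float(out["gpp"]), r_leaf=float(out["r_leaf"]),
        r_sapwood=float(out["r_sapwood"]), r_fineroot=float(out["r_fineroot"]),
        npp=float(out["npp"]), tau_leaf=float(out["tau_leaf"]),
        tau_sapwood=float(out["tau_sapwood"]),
        tau_heartwood=float(out["tau_heartwood"]),
        tau_coarseroot=float(out["tau_coarseroot"]),
        tau_fineroot=float(out["tau_fineroot"]), ncg=float(out["ncg"]),
        aet_monthly=np.asarray(out["aet_monthly"], float),
        lambda_monthly=np.asarray(out["lambda_monthly"], float),
        phi=float(out["phi"]), pools=pools)
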