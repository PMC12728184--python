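"""Independent scalar reference implementation of the annual carbon balance.

Pure-Python re-coding of the documented model formulas (leaf economics,
niche stress, light-use-efficiency photosynthesis, supply/demand water
closure, respiration, turnover, net carbon gain), written with explicit
per-month loops and scipy's brentq root finder.  Used as the
double-implementation oracle for the vectorised production code: both
sides implement the same documented equations but share no code path.
"""

import math

from scipy.optimize import brentq

DAYS = 365.25 / 12.0


def _day_length(lat_deg, doy):
    decl = math.radians(-23.44 * math.cos(2.0 * math.pi * (doy + 10.0) / 365.25))
    lat = math.radians(lat_deg)
    cos_h0 = -math.tan(lat) * math.tan(decl)
    cos_h0 = min(1.0, max(-1.0, cos_h0))
    return 24.0 / math.pi * math.acos(cos_h0)


def _e_eq(t, rsds, p):
    s = 4098.0 * 0.6108 * math.exp(17.27 * t / (t + 237.3)) / (t + 237.3) ** 2
    rn_mj = p.net_sw_fraction * max(rsds, 0.0) * 0.0864
    return s / (s + 0.0665) * rn_mj / 2.45


def _g_resp(t, p):
    return math.exp(p.resp_e0 * (1.0 / p.resp_t1 - 1.0 / (t + p.resp_t2)))


def _f_temp(t, p):
    up = (t - p.t_photo_min) / (p.t_photo_opt_lo - p.t_photo_min)
    down = (p.t_photo_max - t) / (p.t_photo_max - p.t_photo_opt_hi)
    return min(1.0, max(0.0, min(up, down)))


def _gamma_star(t, p):
    return p.gamma_star25 * p.q10_gamma_star ** ((t - 25.0) / 10.0)


def reference_monthly_photosynthesis(apar, t, dayl, pa_ppm, lam, p,
                                     r_leaf_day=0.0, height=None):
    """(a_gross g C m-2 month-1, a_dt g C m-2 day-1) for one month."""
    ca = pa_ppm if p.co2_fertilisation else p.co2_ref_ppm
    gamma = _gamma_star(t, p)
    fc = max((lam * ca - gamma) / (lam * ca + 2.0 * gamma), 0.0)
    if height is None:
        f_hyd = 1.0
    else:
        f_hyd = (1.0 / (1.0 + (height / p.h_hydraulic) ** 2)
                 * (1.0 - p.understory_loss * math.exp(-height / p.h_understory)))
    a_daily = (p.lue_max * _f_temp(t, p) * f_hyd * fc
               * min(apar * 0.0864, p.apar_sat_mj))
    return a_daily * DAYS, max(a_daily - r_leaf_day, 0.0)


def reference_water_residuals(height, c_leaf, a_ll, deciduous, root_shoot,
                              niche, t_m, p_m, r_m, lat, p_a, p,
                              lam_monthly):
    """|E_demand(lambda) - E_supply| (mm day-1) for a given monthly lambda
    series, plus a mask of months where the root is interior (genuinely
    water-limited).  Used to verify the production root-finder."""
    sla = (2.0e-4 / p.dm_c) * 10.0 ** (2.25 - 0.5 * math.log10(a_ll * 12.0))
    leaf_area = c_leaf * sla
    ca_crown = max(p.k_ca * c_leaf ** p.exp_ca_leaf * height ** p.exp_ca_height
                   + p.k_ca_h * height, p.ca_min)
    lai = leaf_area / ca_crown
    t_min_l, t_max_l = min(t_m), max(t_m)
    t_mean_l = sum(t_m) / 12.0
    k_n = p.k_nichebreadth
    phi = min(math.exp(-k_n * (t_max_l - niche[1]) ** 2),
              math.exp(-k_n * (t_min_l - niche[0]) ** 2),
              math.exp(-k_n * (t_mean_l - niche[2]) ** 2))
    if deciduous and a_ll < 1.0:
        k_ext = p.k_ext_deciduous
    elif a_ll > 4.0:
        k_ext = p.k_ext_longleaf
    else:
        k_ext = p.k_ext_default
    ca_ppm = p_a if p.co2_fertilisation else p.co2_ref_ppm
    ca_frac = ca_ppm * 1e-6
    f_hyd = (1.0 / (1.0 + (height / p.h_hydraulic) ** 2)
             * (1.0 - p.understory_loss * math.exp(-height / p.h_understory)))
    residuals, interior = [], []
    for m in range(12):
        t, pr, rs = t_m[m], p_m[m], r_m[m]
        grow = (t > p.t_grow) if deciduous else True
        lai_m = lai if grow else 0.0
        apar = 0.5 * rs * (1.0 - math.exp(-k_ext * lai_m)) \
            * p.alpha_leaf_stand * phi
        doy = m * DAYS + DAYS / 2.0
        dayl = _day_length(lat, doy)
        k_conv = 22.414 / (12.011 * max(dayl, 1e-3) * 3600.0)
        rl_day = p.k_resp_leaf * lai_m * _g_resp(t, p) / 12.0 / DAYS
        gamma = _gamma_star(t, p)
        cpot = (p.lue_max * _f_temp(t, p) * f_hyd
                * min(apar * 0.0864, p.apar_sat_mj))
        e_eq = _e_eq(t, rs, p)
        supply = pr / DAYS
        lam = lam_monthly[m]
        fc = max((lam * ca_ppm - gamma) / (lam * ca_ppm + 2.0 * gamma), 0.0)
        adt = max(cpot * fc - rl_day, 0.0) * k_conv
        gc = 1.6 * adt / (ca_frac * (1.0 - lam)) + p.g_min
        demand = e_eq * p.alpha_m / (1.0 + p.g_m / gc)
        residuals.append(abs(demand - supply))
        interior.append(p.lambda_min + 1e-9 < lam < p.lambda_max - 1e-9)
    return residuals, interior


def reference_annual_balance(height, c_leaf, a_ll, deciduous, root_shoot,
                             niche, t_m, p_m, r_m, lat, p_a, p):
    """Full scalar annual balance; returns a dict mirroring the production
    keys (gpp, npp, ncg, tau_*, r_*, lambda_monthly, aet_monthly...)."""
    sla = (2.0e-4 / p.dm_c) * 10.0 ** (2.25 - 0.5 * math.log10(a_ll * 12.0))
    leaf_area = c_leaf * sla
    ca_crown = max(p.k_ca * c_leaf ** p.exp_ca_leaf * height ** p.exp_ca_height
                   + p.k_ca_h * height, p.ca_min)
    c_sap = p.k_sapwood * leaf_area * height + p.k_struct * ca_crown * height
    c_heart = p.k_heartwood * leaf_area * height ** 2
    c_croot = p.k_coarseroot * (c_sap + c_heart)
    c_froot = root_shoot * c_leaf
    lai = leaf_area / ca_crown

    t_min_l, t_max_l = min(t_m), max(t_m)
    t_mean_l = sum(t_m) / 12.0
    k_n = p.k_nichebreadth
    phi = min(math.exp(-k_n * (t_max_l - niche[1]) ** 2),
              math.exp(-k_n * (t_min_l - niche[0]) ** 2),
              math.exp(-k_n * (t_mean_l - niche[2]) ** 2))

    if deciduous and a_ll < 1.0:
        k_ext = p.k_ext_deciduous
    elif a_ll > 4.0:
        k_ext = p.k_ext_longleaf
    else:
        k_ext = p.k_ext_default

    ca_ppm = p_a if p.co2_fertilisation else p.co2_ref_ppm
    ca_frac = ca_ppm * 1e-6
    f_hyd = (1.0 / (1.0 + (height / p.h_hydraulic) ** 2)
             * (1.0 - p.understory_loss * math.exp(-height / p.h_understory)))

    gpp = 0.0
    r_leaf = 0.0
    lam_monthly, aet_monthly = [], []
    g_sum = 0.0
    for m in range(12):
        t, pr, rs = t_m[m], p_m[m], r_m[m]
        grow = (t > p.t_grow) if deciduous else True
        lai_m = lai if grow else 0.0
        apar = 0.5 * rs * (1.0 - math.exp(-k_ext * lai_m)) \
            * p.alpha_leaf_stand * phi
        doy = m * DAYS + DAYS / 2.0
        dayl = _day_length(lat, doy)
        k_conv = 22.414 / (12.011 * max(dayl, 1e-3) * 3600.0)
        g_m_resp = _g_resp(t, p)
        g_sum += g_m_resp
        rl_m = p.k_resp_leaf * lai_m * g_m_resp / 12.0
        rl_day = rl_m / DAYS
        gamma = _gamma_star(t, p)
        cpot = (p.lue_max * _f_temp(t, p) * f_hyd
                * min(apar * 0.0864, p.apar_sat_mj))
        e_eq = _e_eq(t, rs, p)
        supply = pr / DAYS

        def demand(lam):
            fc = max((lam * ca_ppm - gamma) / (lam * ca_ppm + 2.0 * gamma), 0.0)
            adt = max(cpot * fc - rl_day, 0.0) * k_conv
            gc = 1.6 * adt / (ca_frac * (1.0 - lam)) + p.g_min
            return e_eq * p.alpha_m / (1.0 + p.g_m / gc)

        if supply < demand(p.lambda_max):
            if demand(p.lambda_min) >= supply:
                lam = p.lambda_min
            else:
                lam = brentq(lambda x: demand(x) - supply,
                             p.lambda_min, p.lambda_max,
                             xtol=1e-15, rtol=8.9e-16)
        else:
            lam = p.lambda_max
        fc = max((lam * ca_ppm - gamma) / (lam * ca_ppm + 2.0 * gamma), 0.0)
        gpp += cpot * fc * DAYS
        r_leaf += rl_m
        lam_monthly.append(lam)
        aet_monthly.append(min(supply, demand(lam)) * DAYS)

    g_year = g_sum / 12.0
    r_sap = p.k_resp_sapwood * (c_sap / p.cn_sapwood / ca_crown) * g_year
    r_root = p.k_resp_fineroot * (c_froot / p.cn_fineroot / ca_crown) * g_year
    npp = (1.0 - p.r_gr) * (gpp - r_leaf - r_sap - r_root)

    hd = sum(max(t - p.hd_threshold, 0.0) for t in t_m) / 12.0 / p.hd_scale
    fd = sum(max(p.fd_threshold - t, 0.0) for t in t_m) / 12.0 / p.fd_scale
    if hd + fd > 1.0:
        scale = 1.0 / (hd + fd)
        hd, fd = hd * scale, fd * scale
    damage = min(1.0 + hd + fd, 2.0)
    tau_sap = c_sap * p.f_sapwood * damage
    tau_heart = c_heart * p.f_heartwood * damage
    tau_croot = c_croot * p.f_coarseroot * damage
    tau_leaf = c_leaf * (1.0 if deciduous else 1.0 / a_ll)
    tau_froot = c_froot * (1.0 / a_ll if a_ll > 1.0 else 1.0)
    ncg = npp - (tau_leaf + tau_sap + tau_heart + tau_croot
                 + tau_froot) / ca_crown
    return {
        "gpp": gpp, "r_leaf": r_leaf, "r_sapwood": r_sap,
        "r_fineroot": r_root, "npp": npp, "ncg": ncg, "phi": phi,
        "tau_leaf": tau_leaf, "tau_sapwood": tau_sap,
        "tau_heartwood": tau_heart, "tau_coarseroot": tau_croot,
        "tau_fineroot": tau_froot, "lambda_monthly": lam_monthly,
        "aet_monthly": aet_monthly, "crown_area": ca_crown,
    }
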