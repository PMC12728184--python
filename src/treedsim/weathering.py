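"""Soil carbon and vegetation-enhanced silicate weathering diagnostics.

Soil carbon is a steady-state stock balancing NPP inputs against
temperature-dependent (Q10) heterotrophic respiration.  Silicate
weathering follows the deep-time box-model formulation: erosion supplies
fresh mineral surface, a kinetic bracket (Arrhenius temperature term,
runoff saturation, regolith-age term) converts at most the eroded cation
supply, and vegetation enhances the flux up to six-fold between bare
ground and dense forest.  Global CO2 consumption scales a present-day-like
baseline by the ratio of the global cation flux to its pre-event value.
"""

from __future__ import annotations

import numpy as np

from .params import WeatheringParams

__all__ = [
    "soil_carbon",
    "erosion",
    "biomass_norm",
    "vegetation_weathering_factor",
    "silicate_weathering",
    "co2_consumption",
    "calibrate_erosion_scale",
]


def soil_carbon(npp, t_mean, params: WeatheringParams | None = None):
    """Steady-state soil carbon stock (g C m-2).

    C_soil = NPP / (k * Q10^((T-15)/10)); negative NPP is clamped to zero
    (a dying stand feeds no steady-state stock).
    """
    p = params or WeatheringParams()
    npp = np.maximum(np.asarray(npp, dtype=float), 0.0)
    t = np.asarray(t_mean, dtype=float)
    out = npp / (p.k_soil * p.q10 ** ((t - p.t_base) / 10.0))
    return float(out) if out.ndim == 0 else out


def erosion(q, slope, t_mean, k_e: float | None = None,
            params: WeatheringParams | None = None):
    """Local erosion rate: eps = k_e * q^0.31 * s * max(T, 2).

    ``q`` is annual runoff (mm yr-1), ``slope`` dimensionless, ``t_mean``
    degC with a floor of 2 on the temperature factor.  Result in m yr-1
    with the default scale.
    """
    p = params or WeatheringParams()
    k = p.k_e if k_e is None else k_e
    q = np.asarray(q, dtype=float)
    s = np.asarray(slope, dtype=float)
    if np.any(q < 0) or np.any(s < 0):
        raise ValueError("runoff and slope must be non-negative")
    out = k * q ** 0.31 * s * np.maximum(np.asarray(t_mean, dtype=float), 2.0)
    return float(out) if out.ndim == 0 else out


def biomass_norm(biomass_density, bm_ref: float | None = None,
                 params: WeatheringParams | None = None):
    """Normalised biomass indicator in [0, 1].

    1 corresponds to present-day tropical-forest biomass density
    (140 Mg C ha-1); denser stands saturate at 1.
    """
    p = params or WeatheringParams()
    ref = p.bm_ref if bm_ref is None else bm_ref
    bd = np.asarray(biomass_density, dtype=float)
    if np.any(bd < 0):
        raise ValueError("biomass density must be non-negative")
    out = np.minimum(bd / ref, 1.0)
    return float(out) if out.ndim == 0 else out


def vegetation_weathering_factor(bm_norm, noplant: float | None = None,
                                 params: WeatheringParams | None = None):
    """Vegetation weathering enhancement f_BM = (1 - BM_norm) NOPLANT + BM_norm.

    Affine between the bare-ground fraction (NOPLANT = 1/6, i.e. a
    maximum six-fold enhancement by vegetation) and 1 at full biomass.
    """
    p = params or WeatheringParams()
    np_ = p.noplant if noplant is None else noplant
    bm = np.asarray(bm_norm, dtype=float)
    out = (1.0 - np.minimum(bm, 1.0)) * np_ + np.minimum(bm, 1.0)
    return float(out) if out.ndim == 0 else out


def silicate_weathering(eps, q, t_kelvin, f_bm,
                        params: WeatheringParams | None = None,
                        return_terms: bool = False):
    """Cation release flux from silicate weathering.

    omega = chi_m * eps * (1 - exp[-K * A(T) * R(q) * G(eps)]) * f_BM with
    the Arrhenius factor A = exp(Ea/R T0 - Ea/R T), the runoff saturation
    R = 1 - exp(-k_w q) (q in mm yr-1) and the regolith-age factor
    G = (z/eps)^(sigma+1)/(sigma+1).  eps = 0 yields 0 by continuity.
    """
    p = params or WeatheringParams()
    if p.sigma == -1.0:
        raise ValueError("sigma = -1 is a removable singularity; not supported")
    eps = np.asarray(eps, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("runoff must be non-negative")
    t = np.asarray(t_kelvin, dtype=float)
    arrhenius = np.exp(p.e_a / (p.r_gas * p.t0_kelvin) - p.e_a / (p.r_gas * t))
    runoff_f = 1.0 - np.exp(-p.k_w * q)
    eps_safe = np.where(eps > 0, eps, 1.0)
    regolith = (p.z_regolith / eps_safe) ** (p.sigma + 1.0) / (p.sigma + 1.0)
    bracket = 1.0 - np.exp(-p.big_k * arrhenius * runoff_f * regolith)
    omega = np.where(eps > 0,
                     p.chi_m * eps * bracket * np.asarray(f_bm, dtype=float),
                     0.0)
    omega = float(omega) if omega.ndim == 0 else omega
    if return_terms:
        return omega, {"arrhenius": arrhenius, "runoff": runoff_f,
                       "regolith": regolith, "bracket": bracket}
    return omega


def co2_consumption(omega_global, omega_ref, k_silw: float | None = None,
                    params: WeatheringParams | None = None):
    """Global CO2 consumption by silicate weathering (mol C yr-1).

    F = k_silw * omega/omega_ref, with omega_ref the area-integrated
    cation flux of the pre-event steady state.
    """
    p = params or WeatheringParams()
    k = p.k_silw if k_silw is None else k_silw
    if omega_ref <= 0:
        raise ValueError("reference weathering flux must be positive")
    out = k * np.asarray(omega_global, dtype=float) / omega_ref
    return float(out) if out.ndim == 0 else out


def calibrate_erosion_scale(q, slope, t_mean, area_weights,
                            params: WeatheringParams | None = None) -> float:
    """Choose k_e so the area-weighted mean erosion hits the configured
    present-day-like target (params.erosion_target, m yr-1)."""
    p = params or WeatheringParams()
    base = erosion(q, slope, t_mean, k_e=1.0, params=p)
    w = np.asarray(area_weights, dtype=float)
    mean_base = float(np.sum(base * w) / np.sum(w))
    if mean_base <= 0:
        raise ValueError("cannot calibrate erosion on a zero field")
    return p.erosion_target / mean_base
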