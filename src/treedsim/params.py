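"""Model parameter tables.

All tunable constants of the vegetation, soil-carbon and weathering models
live here, grouped into frozen dataclasses with documented defaults.  The
values printed in the main text of the underlying model description
(dry-matter carbon content, Priestley-Taylor coefficient, niche-breadth
levels, Q10 of soil respiration, weathering calibration constants, ...) are
fixed defaults; internals that common dynamic global vegetation models keep
in supplementary tables (light-use efficiency, respiration coefficients,
allometric exponents) are documented LPJ-style defaults calibrated once to
present-day-like vegetation (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import yaml

__all__ = [
    "PhysiologyParams",
    "OptimiserParams",
    "WeatheringParams",
    "load_config",
    "params_from_mapping",
]


@dataclass(frozen=True)
class PhysiologyParams:
    """Constants of the per-cell annual carbon balance.

    Fluxes are g C per m2 of crown area per year unless stated otherwise;
    pools are g C per plant.
    """

    # -- leaf economics ----------------------------------------------------
    dm_c: float = 0.47              # g C per g dry matter
    a_ll_min: float = 1.0 / 12.0    # yr, leaf-longevity search bound
    a_ll_max: float = 10.0          # yr

    # -- light capture -----------------------------------------------------
    alpha_leaf_stand: float = 0.5   # leaf-to-stand photosynthesis scaling
    # light extinction: 0.6 deciduous a_ll<1; 0.4 if a_ll>4; else 0.5
    k_ext_deciduous: float = 0.6
    k_ext_longleaf: float = 0.4
    k_ext_default: float = 0.5

    # -- climatic niche ----------------------------------------------------
    k_nichebreadth: float = 0.03    # Gaussian niche penalty, degC^-2; {0, 0.03, 0.10}

    # -- photosynthesis (light-use-efficiency form) ------------------------
    lue_max: float = 2.8            # g C per MJ APAR at reference conditions
    apar_sat_mj: float = 7.0        # MJ m-2 day-1; Rubisco-limited capacity cap
    gamma_star25: float = 42.75     # ppm, CO2 compensation point at 25 degC
    q10_gamma_star: float = 1.7     # temperature response of gamma*
    t_photo_min: float = 0.0        # degC; assimilation zero at/below
    t_photo_opt_lo: float = 12.0    # degC; full assimilation from here ...
    t_photo_opt_hi: float = 38.0    # degC; ... to here
    t_photo_max: float = 55.0       # degC; assimilation zero at/above
    co2_fertilisation: bool = True
    co2_ref_ppm: float = 680.0      # reference CO2 when fertilisation is off

    # -- water balance -----------------------------------------------------
    alpha_m: float = 1.391          # Priestley-Taylor coefficient
    g_m: float = 3.26               # mm s-1, conductance scaling factor
    g_min: float = 0.3              # mm s-1, minimum canopy conductance
    lambda_max: float = 0.8         # max ci:ca ratio (non-water-limited)
    lambda_min: float = 0.02        # lower search bound for ci:ca
    net_sw_fraction: float = 0.65   # fraction of RSDS available as net radiation

    # -- respiration -------------------------------------------------------
    r_gr: float = 0.25              # growth respiration fraction
    cn_leaf: float = 29.0           # tissue C:N ratios, g C per g N
    cn_sapwood: float = 330.0
    cn_fineroot: float = 29.0
    k_resp_leaf: float = 30.0       # g C per m2 leaf per yr at g(T)=1
                                    # (area-based: leaf N per area is ~constant
                                    # across the leaf economics spectrum)
    k_resp_sapwood: float = 1.2
    k_resp_fineroot: float = 5.0
    resp_e0: float = 308.56         # Lloyd-Taylor activation parameters
    resp_t1: float = 56.02
    resp_t2: float = 46.02

    # -- turnover ----------------------------------------------------------
    f_sapwood: float = 0.05         # yr-1
    f_heartwood: float = 0.01       # yr-1
    f_coarseroot: float = 0.05      # yr-1
    hd_threshold: float = 35.0      # degC, heat-damage onset (monthly mean)
    fd_threshold: float = -5.0      # degC, frost-damage onset
    hd_scale: float = 10.0          # degC of mean annual excess for full damage
    fd_scale: float = 15.0

    # -- phenology ---------------------------------------------------------
    t_grow: float = 3.0             # degC; deciduous growing-season threshold
    months_cold_deciduous: int = 3  # > this many months below t_grow allows deciduousness

    # -- allometry ---------------------------------------------------------
    k_ca: float = 0.013             # crown area leaf-mass coefficient
    exp_ca_leaf: float = 0.75       # CA ~ k_ca C_leaf^exp H^exp + k_ca_h H
    exp_ca_height: float = 0.25
    k_ca_h: float = 0.1            # m2 crown per m height (tall crowns are wide)
    ca_min: float = 1.0             # m2, structural floor
    k_sapwood: float = 55.0         # pipe-model term, g C per (m2 leaf * m)
    k_struct: float = 50.0          # structural sapwood, g C per (m2 crown * m)
    k_heartwood: float = 2.2        # g C per (m2 leaf * m^2)
    k_coarseroot: float = 0.25      # fraction of (sap+heart) below ground
    root_shoot: float = 1.0         # fine-root : leaf carbon ratio (r:s)
    h_hydraulic: float = 150.0      # m; photosynthesis scaled by 1/(1+(H/h)^2)
    understory_loss: float = 0.3    # light-capture deficit of a zero-height
    h_understory: float = 10.0      # stand, decaying as exp(-H/h_understory)

    # -- height search -----------------------------------------------------
    h_min: float = 0.5              # m
    h_max: float = 80.0             # m
    ncg_npp_ratio: float = 0.2      # reproductive-success threshold NCG/NPP
    h_tol: float = 0.05             # m, bisection tolerance on h_max


@dataclass(frozen=True)
class OptimiserParams:
    """Differential-evolution settings for the trait search."""

    popsize: int = 16
    generations: int = 30
    mutation: float = 0.7
    recombination: float = 0.9
    c_leaf_lo: float = 10.0         # g C, log-uniform search bounds
    c_leaf_hi: float = 1.0e5
    seed_const: int = 715827883     # fixed entropy for environment-determined optima
    tol: float = 0.0                # no early stopping by default (determinism)


@dataclass(frozen=True)
class WeatheringParams:
    """Soil-carbon and silicate-weathering constants."""

    # soil carbon (steady-state Q10 model)
    k_soil: float = 1.0 / 16.0      # yr-1, heterotrophic decomposition rate
    q10: float = 1.75
    t_base: float = 15.0            # degC

    # silicate weathering
    chi_m: float = 0.1              # cation abundance in bedrock
    z_regolith: float = 10.0        # m
    e_a: float = 20_000.0           # J mol-1, apparent activation energy
    r_gas: float = 8.314            # J mol-1 K-1
    t0_kelvin: float = 288.15       # K, standard temperature
    big_k: float = 6.0e-5
    k_w: float = 1.0e-3             # per (mm yr-1) of runoff
    sigma: float = -0.1
    k_e: float = 2.0e-7             # erosion scale; recalibrated per world
    erosion_target: float = 1.0e-4  # m yr-1, present-day-like mean erosion
    noplant: float = 1.0 / 6.0      # bare-ground weathering fraction
    bm_ref: float = 140.0           # Mg C ha-1, tropical-forest biomass density
    k_silw: float = 1.0e13          # mol C yr-1, baseline CO2 consumption


def _coerce(dc_cls, mapping: Mapping[str, Any]):
    names = {f.name for f in fields(dc_cls)}
    unknown = set(mapping) - names
    if unknown:
        raise KeyError(f"unknown {dc_cls.__name__} keys: {sorted(unknown)}")
    return dc_cls(**mapping)


def params_from_mapping(section: Mapping[str, Any] | None, dc_cls):
    """Build a params dataclass from a (possibly empty) config mapping."""
    return _coerce(dc_cls, dict(section or {}))


def load_config(path: str) -> dict:
    """Read a YAML experiment configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TypeError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def with_overrides(params, **kwargs):
    """Return a copy of a frozen params dataclass with fields replaced."""
    return replace(params, **kwargs)
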