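"""Climate and CO2 forcing.

A hyperthermal warming experiment is forced by (i) a piecewise-linear
atmospheric CO2 timeline with a step onset, and (ii) monthly climatologies
obtained by linear interpolation between two endmember climate states (a
cool pre-event and a warm peak state).  A synthetic two-endmember world
generator provides desk-scale test climatologies with an equator-to-pole
temperature gradient, seasonality, wet tropics and storm tracks, solar
geometry radiation, and a prescribed land-mean warming offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0
SOLAR_CONSTANT = 1361.0  # W m-2

__all__ = [
    "ClimatologyGrid",
    "Co2Schedule",
    "petm_co2_schedule",
    "interpolate_climatology",
    "synthetic_world",
    "to_netcdf",
    "from_netcdf",
    "to_csv",
    "from_csv",
    "cell_areas_km2",
]


@dataclass
class ClimatologyGrid:
    """Monthly climate + static fields for one CO2 level.

    Monthly arrays are shaped (n_lat, n_lon, 12); ``slope`` and
    ``land_mask`` are (n_lat, n_lon).  ``co2`` is the ppm tag of the
    endmember.
    """

    lat: np.ndarray
    lon: np.ndarray
    land_mask: np.ndarray
    t_monthly: np.ndarray          # degC
    p_monthly: np.ndarray          # mm month-1
    rsds_monthly: np.ndarray       # W m-2
    slope: np.ndarray              # dimensionless
    co2: float                     # ppm

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        for name in ("t_monthly", "p_monthly", "rsds_monthly"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.lat.size, self.lon.size, 12):
                raise ValueError(f"{name} must have shape (n_lat, n_lon, 12)")
            setattr(self, name, arr)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self.slope = np.asarray(self.slope, dtype=float)
        dlat, dlon = np.diff(self.lat), np.diff(self.lon)
        if not (np.all(dlat > 0) or np.all(dlat < 0)):
            raise ValueError("lat must be strictly monotone")
        if not (np.all(dlon > 0) or np.all(dlon < 0)):
            raise ValueError("lon must be strictly monotone")
        land = self.land_mask
        for name in ("t_monthly", "p_monthly", "rsds_monthly"):
            if np.any(~np.isfinite(getattr(self, name)[land])):
                raise ValueError(f"missing values on land in {name}")
        if np.any(self.p_monthly < 0):
            raise ValueError("precipitation must be non-negative")
        if np.any(self.rsds_monthly < 0):
            raise ValueError("shortwave radiation must be non-negative")

    def congruent_with(self, other: "ClimatologyGrid") -> bool:
        return (self.lat.shape == other.lat.shape
                and self.lon.shape == other.lon.shape
                and np.allclose(self.lat, other.lat)
                and np.allclose(self.lon, other.lon)
                and np.array_equal(self.land_mask, other.land_mask))


@dataclass(frozen=True)
class Co2Schedule:
    """Piecewise-linear CO2 timeline around a step-warming event (kyr, ppm).

    The onset step sits between t_rel = 0 (last pre-event value) and
    t_rel = step_kyr (first peak value); the peak plateau runs to the end
    of the event body; two linear recovery ramps follow.
    """

    t_pre: float = 50.0            # kyr of pre-event conditions
    co2_pre: float = 680.0
    co2_peak: float = 1590.0
    body_duration: float = 70.0    # kyr at peak after the onset step
    t_recovery1: float = 150.0     # kyr after onset
    co2_recovery1: float = 780.0
    t_end: float = 200.0           # kyr after onset
    co2_end: float = 680.0
    step_kyr: float = 10.0


def petm_co2_schedule(t_rel, schedule: Co2Schedule | None = None):
    """CO2 (ppm) at time ``t_rel`` (kyr relative to the event onset).

    Pre-event level up to and including t_rel = 0; the peak level from
    just after the onset through the event body; then linear declines to
    the two recovery anchors.  Out-of-range times raise ValueError.
    """
    s = schedule or Co2Schedule()
    t = np.asarray(t_rel, dtype=float)
    if np.any(t < -s.t_pre) or np.any(t > s.t_end):
        raise ValueError(
            f"t_rel outside schedule range [{-s.t_pre}, {s.t_end}] kyr")
    t_body_end = s.step_kyr + s.body_duration
    out = np.empty_like(t)
    pre = t <= 0.0
    body = (t > 0.0) & (t <= t_body_end)
    rec1 = (t > t_body_end) & (t <= s.t_recovery1)
    rec2 = t > s.t_recovery1
    out[pre] = s.co2_pre
    out[body] = s.co2_peak
    w1 = (t[rec1] - t_body_end) / (s.t_recovery1 - t_body_end)
    out[rec1] = s.co2_peak + w1 * (s.co2_recovery1 - s.co2_peak)
    w2 = (t[rec2] - s.t_recovery1) / (s.t_end - s.t_recovery1)
    out[rec2] = s.co2_recovery1 + w2 * (s.co2_end - s.co2_recovery1)
    return float(out) if out.ndim == 0 else out


def interpolate_climatology(low: ClimatologyGrid, high: ClimatologyGrid,
                            co2: float, log_co2: bool = False) -> ClimatologyGrid:
    """Linear blend of two endmember climatologies at an intermediate CO2.

    Weights are linear in concentration by default (``log_co2=True``
    blends linearly in log CO2 instead); no extrapolation.  Static fields
    (mask, slope) are copied from the low endmember.
    """
    if not low.congruent_with(high):
        raise ValueError("endmember grids are not congruent")
    if not (low.co2 < high.co2):
        raise ValueError("low endmember must have the lower CO2")
    if not (low.co2 <= co2 <= high.co2):
        raise ValueError(f"co2={co2} outside [{low.co2}, {high.co2}]; "
                         "no extrapolation")
    if log_co2:
        w = (np.log(co2) - np.log(low.co2)) / (np.log(high.co2) - np.log(low.co2))
    else:
        w = (co2 - low.co2) / (high.co2 - low.co2)
    blend = lambda a, b: (1.0 - w) * a + w * b
    return ClimatologyGrid(
        lat=low.lat.copy(), lon=low.lon.copy(),
        land_mask=low.land_mask.copy(),
        t_monthly=blend(low.t_monthly, high.t_monthly),
        p_monthly=blend(low.p_monthly, high.p_monthly),
        rsds_monthly=blend(low.rsds_monthly, high.rsds_monthly),
        slope=low.slope.copy(), co2=float(co2))


# ---------------------------------------------------------------------------
# synthetic two-endmember world
# ---------------------------------------------------------------------------

_WORLD_DEFAULTS = dict(
    t_equator=28.0,        # degC mean annual temperature at the equator
    t_gradient=34.0,       # degC equator-to-pole drop (times sin^2 lat)
    seasonal_base=2.0,     # degC seasonal half-amplitude at the equator
    seasonal_polar=16.0,   # additional half-amplitude towards the poles
    p_tropics=170.0,       # mm month-1 tropical rain belt peak
    p_storms=70.0,         # mm month-1 mid-latitude storm tracks
    p_base=25.0,           # mm month-1 background
    p_noise=0.25,          # lognormal sigma of spatial precipitation noise
    transmissivity=0.55,   # surface / top-of-atmosphere shortwave ratio
    land_fraction=0.35,
    land_modes=4,          # number of low-frequency mask modes
    slope_median=0.05,
    slope_sigma=0.8,
    polar_amplification=0.6,   # warming ~ offset*(1 + pa*sin^2 lat), renormalised
    warming_heterogeneity=0.35,  # relative amplitude of the regional warming
                                 # pattern (maritime vs continental contrasts)
    warming_winter_asym=0.4,     # winter-dominated warming: cold months warm
                                 # (1+a) times the annual mean, warm months
                                 # (1-a) times, damping seasonality poleward
    precip_cc_scaling=0.02,    # fractional precip increase per degC local warming
    co2_pre=680.0,
    co2_peak=1590.0,
)


def synthetic_world(n_lat: int, n_lon: int, warming_offset: float,
                    seed: int, params: dict | None = None):
    """Generate congruent (pre, peak) endmember climatologies.

    The pre grid has an equator-to-pole mean-annual-temperature gradient,
    a seasonal cycle growing with |lat|, wet tropics plus mid-latitude
    storm tracks, radiation from daily-mean solar geometry, and a
    seed-reproducible land mask and slope field.  The peak grid applies a
    poleward-amplified warming whose land-area-weighted mean equals
    ``warming_offset`` exactly, with a modest precipitation scaling.
    """
    if n_lat < 4 or n_lon < 4:
        raise ValueError("need at least a 4 x 4 grid")
    p = dict(_WORLD_DEFAULTS)
    p.update(params or {})
    rng = np.random.default_rng(seed)

    dlat = 180.0 / n_lat
    dlon = 360.0 / n_lon
    lat = -90.0 + dlat * (np.arange(n_lat) + 0.5)
    lon = dlon * (np.arange(n_lon) + 0.5)
    lat2 = lat[:, None] * np.ones((1, n_lon))
    sin2 = np.sin(np.deg2rad(lat2)) ** 2

    # land mask from a few seeded low-frequency modes, thresholded to the
    # requested land fraction (area-weighted)
    field = np.zeros((n_lat, n_lon))
    for _ in range(int(p["land_modes"])):
        kx = rng.integers(1, 4)
        ky = rng.integers(1, 3)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.cos(np.deg2rad(lon)[None, :] * kx + phx) \
            * np.cos(np.deg2rad(lat)[:, None] * 2 * ky + phy)
    field += 0.3 * rng.standard_normal((n_lat, n_lon))
    w_area = np.cos(np.deg2rad(lat2))
    order = np.argsort(field, axis=None)[::-1]
    cum = np.cumsum(w_area.ravel()[order])
    n_keep = int(np.searchsorted(cum, p["land_fraction"] * w_area.sum()))
    land_mask = np.zeros(n_lat * n_lon, dtype=bool)
    land_mask[order[:max(n_keep, 4)]] = True
    land_mask = land_mask.reshape(n_lat, n_lon)

    # temperature: zonal mean-annual profile + hemisphere-phased seasonality
    t_ann = p["t_equator"] - p["t_gradient"] * sin2
    amp = p["seasonal_base"] + p["seasonal_polar"] * np.abs(np.sin(np.deg2rad(lat2)))
    month_phase = np.cos(2.0 * np.pi * (np.arange(12) - 6.0) / 12.0)
    hemi = np.where(lat2 >= 0, 1.0, -1.0)
    t_monthly = (t_ann[:, :, None]
                 + (amp * hemi)[:, :, None] * month_phase[None, None, :])

    # precipitation: tropical belt + storm tracks + background, mild
    # seasonality and seed-reproducible spatial noise
    p_zonal = (p["p_tropics"] * np.exp(-(lat2 / 15.0) ** 2)
               + p["p_storms"] * np.exp(-(((np.abs(lat2) - 45.0) / 12.0) ** 2))
               + p["p_base"])
    p_noise = np.exp(p["p_noise"] * rng.standard_normal((n_lat, n_lon)))
    season_p = 1.0 + 0.15 * (hemi[:, :, None] * month_phase[None, None, :])
    p_monthly = np.maximum(p_zonal[:, :, None] * p_noise[:, :, None] * season_p, 0.0)

    # radiation: daily-mean top-of-atmosphere insolation times transmissivity
    doy = np.arange(12) * (365.25 / 12.0) + 365.25 / 24.0
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25))
    lat_r = np.deg2rad(lat2)[:, :, None]
    cos_h0 = np.clip(-np.tan(lat_r) * np.tan(decl[None, None, :]), -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    q_toa = (SOLAR_CONSTANT / np.pi
             * (h0 * np.sin(lat_r) * np.sin(decl)
                + np.cos(lat_r) * np.cos(decl) * np.sin(h0)))
    rsds_monthly = np.maximum(p["transmissivity"] * q_toa, 0.0)

    slope = np.exp(np.log(p["slope_median"])
                   + p["slope_sigma"] * rng.standard_normal((n_lat, n_lon)))

    pre = ClimatologyGrid(lat=lat, lon=lon, land_mask=land_mask,
                          t_monthly=t_monthly, p_monthly=p_monthly,
                          rsds_monthly=rsds_monthly, slope=slope,
                          co2=float(p["co2_pre"]))

    # peak endmember: poleward-amplified warming with a seeded smooth
    # regional pattern (GCM warming fields are strongly heterogeneous;
    # low-warming regions act as climatic refugia), renormalised so the
    # land-area-weighted mean equals the requested offset exactly
    het = np.zeros((n_lat, n_lon))
    for _ in range(3):
        kx = rng.integers(1, 4)
        ky = rng.integers(1, 3)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        het += rng.uniform(0.4, 1.0) * np.cos(np.deg2rad(lon)[None, :] * kx + phx) \
            * np.cos(np.deg2rad(lat)[:, None] * 2 * ky + phy)
    het = het / max(np.abs(het).max(), 1e-12)
    shape_f = np.maximum((1.0 + p["polar_amplification"] * sin2)
                         * (1.0 + p["warming_heterogeneity"] * het), 0.1)
    wsum = (w_area * land_mask).sum()
    mean_shape = (shape_f * w_area * land_mask).sum() / wsum
    dt = warming_offset * shape_f / mean_shape
    # winter-dominated warming: the annual-mean offset is preserved exactly
    # (the seasonal phase sums to zero over the 12 months)
    dt_monthly = dt[:, :, None] * (1.0 - p["warming_winter_asym"]
                                   * (hemi[:, :, None] * month_phase[None, None, :]))
    p_scale = np.maximum(1.0 + p["precip_cc_scaling"] * dt, 0.0)
    peak = ClimatologyGrid(
        lat=lat.copy(), lon=lon.copy(), land_mask=land_mask.copy(),
        t_monthly=t_monthly + dt_monthly,
        p_monthly=p_monthly * p_scale[:, :, None],
        rsds_monthly=rsds_monthly.copy(), slope=slope.copy(),
        co2=float(p["co2_peak"]))
    return pre, peak


def cell_areas_km2(grid: ClimatologyGrid) -> np.ndarray:
    """Spherical cell areas (km2), shape (n_lat, n_lon)."""
    lat = grid.lat
    dlat = np.abs(np.diff(lat).mean())
    dlon = np.abs(np.diff(grid.lon).mean())
    lo = np.deg2rad(np.clip(lat - dlat / 2.0, -90.0, 90.0))
    hi = np.deg2rad(np.clip(lat + dlat / 2.0, -90.0, 90.0))
    band = EARTH_RADIUS_KM ** 2 * np.deg2rad(dlon) * (np.sin(hi) - np.sin(lo))
    return np.abs(band)[:, None] * np.ones((1, grid.lon.size))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _to_dataset(grid: ClimatologyGrid) -> xr.Dataset:
    return xr.Dataset(
        {
            "tas": (("month", "lat", "lon"), grid.t_monthly.transpose(2, 0, 1)),
            "pr": (("month", "lat", "lon"), grid.p_monthly.transpose(2, 0, 1)),
            "rsds": (("month", "lat", "lon"),
                     grid.rsds_monthly.transpose(2, 0, 1)),
            "slope": (("lat", "lon"), grid.slope),
            "land_mask": (("lat", "lon"), grid.land_mask.astype(np.int8)),
        },
        coords={"month": np.arange(1, 13), "lat": grid.lat, "lon": grid.lon},
        attrs={"co2_ppm": grid.co2},
    )


def to_netcdf(grid: ClimatologyGrid, path: str | Path) -> None:
    """Write a climatology as a CF-style NetCDF file (dims month, lat, lon)."""
    _to_dataset(grid).to_netcdf(path, engine="scipy")


def from_netcdf(path: str | Path) -> ClimatologyGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return ClimatologyGrid(
        lat=ds["lat"].values, lon=ds["lon"].values,
        land_mask=ds["land_mask"].values.astype(bool),
        t_monthly=ds["tas"].values.transpose(1, 2, 0),
        p_monthly=ds["pr"].values.transpose(1, 2, 0),
        rsds_monthly=ds["rsds"].values.transpose(1, 2, 0),
        slope=ds["slope"].values, co2=float(ds.attrs["co2_ppm"]))


def to_csv(grid: ClimatologyGrid, path: str | Path) -> None:
    """Long-format CSV (lat, lon, month, variable, value) for tiny fixtures."""
    rows = []
    for name, arr in (("tas", grid.t_monthly), ("pr", grid.p_monthly),
                      ("rsds", grid.rsds_monthly)):
        for i, la in enumerate(grid.lat):
            for j, lo in enumerate(grid.lon):
                for m in range(12):
                    rows.append((la, lo, m + 1, name, arr[i, j, m]))
    for name, arr in (("slope", grid.slope),
                      ("land_mask", grid.land_mask.astype(float))):
        for i, la in enumerate(grid.lat):
            for j, lo in enumerate(grid.lon):
                rows.append((la, lo, 0, name, arr[i, j]))
    df = pd.DataFrame(rows, columns=["lat", "lon", "month", "variable", "value"])
    df.attrs["co2_ppm"] = grid.co2
    with open(path, "w") as fh:
        fh.write(f"# co2_ppm={grid.co2}\n")
        df.to_csv(fh, index=False)


def from_csv(path: str | Path) -> ClimatologyGrid:
    with open(path) as fh:
        header = fh.readline().strip()
        co2 = float(header.split("=", 1)[1]) if header.startswith("#") else np.nan
        df = pd.read_csv(fh)
    lat = np.sort(df["lat"].unique())
    lon = np.sort(df["lon"].unique())
    ii = {v: i for i, v in enumerate(lat)}
    jj = {v: j for j, v in enumerate(lon)}
    monthly = {v: np.zeros((lat.size, lon.size, 12))
               for v in ("tas", "pr", "rsds")}
    static = {v: np.zeros((lat.size, lon.size)) for v in ("slope", "land_mask")}
    for row in df.itertuples(index=False):
        i, j = ii[row.lat], jj[row.lon]
        if row.variable in monthly:
            monthly[row.variable][i, j, int(row.month) - 1] = row.value
        else:
            static[row.variable][i, j] = row.value
    return ClimatologyGrid(
        lat=lat, lon=lon, land_mask=static["land_mask"].astype(bool),
        t_monthly=monthly["tas"], p_monthly=monthly["pr"],
        rsds_monthly=monthly["rsds"], slope=static["slope"], co2=co2)
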