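"""Seeded synthetic flux-site records and toy driver grids with known truth.

``make_site`` builds daily forcing from sinusoidal seasonal cycles plus
lag-1 autocorrelated weather noise, runs the forward model with known
"true" maximum LUEs to produce observed GPP, then perturbs it with
multiplicative lognormal noise and punches random gaps — giving
recovery targets for the calibration machinery and screening rules.

``make_grid`` builds a small spatially smooth driver stack (LAI,
meteorology, land cover, CO2 ramp) and the matching truth GPP stack
for product-pipeline round-trip tests.

The generators make no attempt to mimic any specific tower site; they
provide physically plausible ranges with controlled ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .core import PftParameters, get_pft_parameters, run_series
from .grid import GridSpec

AR1_COEFF = 0.7  # synoptic persistence of weather noise


@dataclass
class SyntheticSiteConfig:
    pft_code: str = "DBF"
    latitude: float = 45.0
    years: int = 3
    start_year: int = 2001
    true_eps_msh: float = 3.75
    true_eps_msu: float = 0.92
    lai_min: float = 0.3
    lai_max: float = 5.0
    lai_peak_doy: int = 200
    t_mean_K: float = 283.15
    t_amplitude_K: float = 12.0
    t_noise_K: float = 2.0
    vpd_mean_kPa: float = 0.9
    vpd_amplitude_kPa: float = 0.6
    vpd_noise_kPa: float = 0.3
    clearness_mean: float = 0.55
    clearness_noise: float = 0.15
    co2_start_ppm: float = 370.0
    co2_trend_ppm_per_year: float = 2.0
    noise_cv: float = 0.0
    gap_fraction: float = 0.0
    seed: int = field(default=None)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible synthesis")


def _ar1(rng, n, sigma, coeff=AR1_COEFF):
    eps = rng.normal(0.0, sigma * np.sqrt(1.0 - coeff ** 2), n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sigma)
    for i in range(1, n):
        out[i] = coeff * out[i - 1] + eps[i]
    return out


def _seasonal(doy, peak_doy, amplitude):
    return amplitude * np.cos(2.0 * np.pi * (doy - peak_doy) / 365.25)


def make_site(config: SyntheticSiteConfig):
    """Generate one synthetic site as (records, truth) DataFrames.

    ``records`` carries the standardized forcing columns plus noisy,
    gappy ``gpp_obs``; ``truth`` keeps the noise-free daily GPP triple
    and the generating parameters for recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(f"{config.start_year}-01-01",
                          periods=round(config.years * 365.25), freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy(float)
    year_frac = (dates - dates[0]).days / 365.25

    hemisphere_peak = config.lai_peak_doy
    t_air = (config.t_mean_K + _seasonal(doy, hemisphere_peak, config.t_amplitude_K)
             + _ar1(rng, n, config.t_noise_K))
    vpd = np.maximum(
        config.vpd_mean_kPa + _seasonal(doy, hemisphere_peak, config.vpd_amplitude_kPa)
        + _ar1(rng, n, config.vpd_noise_kPa), 0.01)
    clearness = np.clip(
        config.clearness_mean + _ar1(rng, n, config.clearness_noise), 0.05, 0.95)
    lai_season = 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - config.lai_peak_doy) / 365.25))
    lai = config.lai_min + (config.lai_max - config.lai_min) * lai_season
    co2 = config.co2_start_ppm + config.co2_trend_ppm_per_year * year_frac

    from .solar import SECONDS_PER_DAY, daylength_seconds, solar_cos_zenith
    cos_theta = np.asarray(solar_cos_zenith(config.latitude, doy))
    daylen = np.asarray(daylength_seconds(config.latitude, doy))
    sw_daytime = clearness * 1367.0 * cos_theta
    sw_down = sw_daytime * daylen / SECONDS_PER_DAY  # 24-h mean flux

    records = pd.DataFrame({
        "date": dates, "doy": doy.astype(int), "site": f"SYN-{config.seed}",
        "latitude": config.latitude, "t_air_K": t_air, "vpd": vpd,
        "sw_down": sw_down, "par": 0.43 * sw_down,
        "co2_ppm": co2, "lai": lai,
    })

    true_params = get_pft_parameters(config.pft_code)
    true_params = PftParameters(**{
        **true_params.__dict__,
        "eps_msh": config.true_eps_msh, "eps_msu": config.true_eps_msu})
    sim = run_series(records, true_params)
    gpp_true = sim["gpp"].to_numpy()

    gpp_obs = gpp_true.copy()
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + config.noise_cv ** 2))
        gpp_obs = gpp_obs * rng.lognormal(-sigma ** 2 / 2.0, sigma, n)
    if config.gap_fraction > 0:
        gaps = rng.random(n) < config.gap_fraction
        gpp_obs = np.where(gaps, np.nan, gpp_obs)
    records["gpp_obs"] = gpp_obs

    truth = sim.assign(gpp_true=gpp_true,
                       eps_msh_true=config.true_eps_msh,
                       eps_msu_true=config.true_eps_msu)
    return records, truth


def site_to_flux_csv(records: pd.DataFrame, path):
    """Write a synthetic record frame in the tower-table layout the
    forcing reader consumes (-9999 missing sentinel)."""
    out = pd.DataFrame({
        "TIMESTAMP": pd.to_datetime(records["date"]).dt.strftime("%Y%m%d"),
        "SITE_ID": records["site"],
        "LATITUDE": records["latitude"],
        "TA_F": records["t_air_K"] - 273.15,
        "VPD_F": records["vpd"] * 10.0,
        "SW_IN_F": records["sw_down"],
        "CO2_F_MDS": records["co2_ppm"],
        "LAI": records["lai"],
        "GPP_DT_CUT_MEAN": records["gpp_obs"],
    })
    out = out.fillna(-9999.0)
    out.to_csv(path, index=False)
    return path


def make_grid(n_lat=20, n_lon=20, years=3, start_year=2001, pft_code="DBF",
              resolution=0.05, lat0=40.0, lon0=-100.0, seed=0):
    """Generate a toy driver grid and its truth GPP stack.

    Returns a dict with daily driver DataArrays (lai, t_air_K, vpd,
    sw_down, co2_ppm), a categorical pft map, a GridSpec, and the
    truth daily GPP stacks (gpp, gpp_sun, gpp_shade) computed by the
    forward model with the shipped parameters for ``pft_code``.
    """
    rng = np.random.default_rng(seed)
    spec = GridSpec(resolution=resolution,
                    lon_min=lon0, lon_max=lon0 + n_lon * resolution,
                    lat_min=lat0, lat_max=lat0 + n_lat * resolution)
    lats, lons = spec.lats, spec.lons
    dates = pd.date_range(f"{start_year}-01-01", periods=round(years * 365.25),
                          freq="D")
    doy = dates.dayofyear.to_numpy(float)

    lat2d = np.repeat(lats[:, None], len(lons), axis=1)
    lon_grad = np.linspace(0.0, 1.0, len(lons))[None, :]
    lai_peak = 4.0 + 1.5 * (lat2d - lats.mean()) / max(np.ptp(lats), 1e-9) + 0.5 * lon_grad
    season = 0.5 * (1.0 + np.cos(2.0 * np.pi * (doy - 200.0) / 365.25))
    lai = 0.3 + (lai_peak[None] - 0.3) * season[:, None, None]

    t_air = (283.15 + 12.0 * np.cos(2.0 * np.pi * (doy - 200.0) / 365.25)[:, None, None]
             - 0.5 * (lat2d - lats.mean())[None]
             + _ar1(rng, len(dates), 1.5)[:, None, None])
    vpd = np.maximum(0.8 + 0.5 * np.cos(2.0 * np.pi * (doy - 200.0) / 365.25)
                     [:, None, None] + _ar1(rng, len(dates), 0.2)[:, None, None],
                     0.01) * np.ones_like(t_air)
    clearness = np.clip(0.55 + _ar1(rng, len(dates), 0.1), 0.05, 0.95)

    from .solar import SECONDS_PER_DAY, daylength_seconds, solar_cos_zenith
    cos_theta = np.stack([np.asarray(solar_cos_zenith(lat2d, d)) for d in doy])
    daylen = np.stack([np.asarray(daylength_seconds(lat2d, d)) for d in doy])
    sw_down = clearness[:, None, None] * 1367.0 * cos_theta * daylen / SECONDS_PER_DAY

    coords = {"time": dates, "lat": lats, "lon": lons}
    dims = ("time", "lat", "lon")
    drivers = {
        "lai": xr.DataArray(lai, coords=coords, dims=dims),
        "t_air_K": xr.DataArray(t_air, coords=coords, dims=dims),
        "vpd": xr.DataArray(vpd, coords=coords, dims=dims),
        "sw_down": xr.DataArray(sw_down, coords=coords, dims=dims),
    }
    co2_monthly = pd.DataFrame({
        "year_month": pd.period_range(dates[0], dates[-1], freq="M").astype(str),
        "co2_ppm": 370.0 + 2.0 * np.arange(len(pd.period_range(dates[0], dates[-1], freq="M"))) / 12.0,
    })
    pft_map = xr.DataArray(np.full((len(lats), len(lons)), pft_code, dtype=object),
                           coords={"lat": lats, "lon": lons}, dims=("lat", "lon"))

    truth = run_grid(drivers, co2_monthly, pft_map)
    return {"drivers": drivers, "co2_monthly": co2_monthly, "pft_map": pft_map,
            "spec": spec, "truth": truth, "dates": dates}


def run_grid(drivers: dict, co2_monthly: pd.DataFrame, pft_map: xr.DataArray,
             params_path=None) -> dict:
    """Run the daily model over a driver stack.

    Pixels are grouped by vegetation type and evaluated vectorized;
    non-vegetated pixels (pft None) yield NaN, distinguishing "no
    vegetation" from "zero flux".  Returns daily (time, lat, lon)
    stacks for gpp, gpp_sun and gpp_shade.
    """
    from .core import load_pft_parameters
    from .canopy import CanopyGeometry, partition_radiation
    from .forcing import SOLAR_CONSTANT
    from .scalars import regulation_scalars
    from .solar import SECONDS_PER_DAY, daylength_seconds, solar_cos_zenith

    all_params = load_pft_parameters(params_path)
    lai = drivers["lai"]
    dates = pd.DatetimeIndex(lai["time"].values)
    lats = lai["lat"].values
    lons = lai["lon"].values
    doy = dates.dayofyear.to_numpy(float)

    month_key = dates.to_period("M").astype(str)
    co2_lookup = dict(zip(co2_monthly["year_month"], co2_monthly["co2_ppm"]))
    co2 = np.array([co2_lookup[m] for m in month_key])

    lat2d = np.repeat(lats[:, None], len(lons), axis=1)
    cos_theta = np.stack([np.asarray(solar_cos_zenith(lat2d, d)) for d in doy])
    daylen = np.stack([np.asarray(daylength_seconds(lat2d, d)) for d in doy])

    shape = (len(dates), len(lats), len(lons))
    out = {k: np.full(shape, np.nan) for k in ("gpp", "gpp_sun", "gpp_shade")}

    pfts = pft_map.values
    for pft in sorted({p for p in pfts.ravel() if p is not None}):
        sel = pfts == pft
        p = all_params[pft]
        lai_v = lai.values[:, sel]
        sw_v = drivers["sw_down"].values[:, sel]
        t_v = drivers["t_air_K"].values[:, sel]
        vpd_v = drivers["vpd"].values[:, sel]
        ct = cos_theta[:, sel]
        dl = daylen[:, sel]
        co2_v = np.broadcast_to(co2[:, None], lai_v.shape)

        active = (dl > 0) & (ct > 0) & (lai_v > 0) & (sw_v > 0)
        g = np.zeros_like(lai_v)
        gs = np.zeros_like(lai_v)
        gsh = np.zeros_like(lai_v)
        if active.any():
            sw_day = sw_v[active] * SECONDS_PER_DAY / dl[active]
            R = np.clip(sw_day / (SOLAR_CONSTANT * ct[active]), 0.0, 1.0)
            geom = CanopyGeometry(lai=lai_v[active], clumping=p.clumping,
                                  albedo=p.albedo, cos_theta=ct[active])
            rad = partition_radiation(0.43 * sw_day, R, geom)
            scal = regulation_scalars(t_v[active], vpd_v[active], co2_v[active],
                                      p.temperature_limits, p.vpd_min, p.vpd_max)
            to_mj = dl[active] * 1e-6
            env = np.asarray(scal.t_s) * np.asarray(scal.w_s) * np.asarray(scal.c_s)
            gsh_a = p.eps_msh * rad.apar_shade * to_mj * env
            gs_a = p.eps_msu * rad.apar_sun * to_mj * env
            gsh[active] = gsh_a
            gs[active] = gs_a
            g[active] = gsh_a + gs_a
        out["gpp"][:, sel] = g
        out["gpp_sun"][:, sel] = gs
        out["gpp_shade"][:, sel] = gsh

    coords = {"time": dates, "lat": lats, "lon": lons}
    return {k: xr.DataArray(v, coords=coords, dims=("time", "lat", "lon"))
            for k, v in out.items()}
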