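"""Daily model forcing: unit conversions, aggregation and flux-record screening.

Builds the daily driver set the model consumes — air temperature, vapor
pressure deficit (VPD), photosynthetically active radiation (PAR), sky
clearness, CO2 and leaf area index (LAI) — from raw meteorology or from
eddy-covariance tower tables, and applies the site-year screening and
gap-filling rules used before calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .solar import solar_cos_zenith

SOLAR_CONSTANT = 1367.0  # W m-2
PAR_FACTOR_DEFAULT = 0.43  # shortwave -> PAR, site-tuned; literature span 0.39-0.53
MISSING_SENTINEL = -9999.0
MAX_MISSING_DAYS_DEFAULT = 60  # "less than 2 months" per variable per year

#: tower-table columns required for a site-year to be usable
REQUIRED_COLUMNS = ("TA_F", "VPD_F", "CO2_F_MDS", "SW_IN_F", "GPP_DT_CUT_MEAN")


def vapor_pressure_saturated(t_air_C):
    """Saturation vapor pressure in kPa (Buck-type exponential form).

    At 0 degC the exponent vanishes and the coefficient 0.61121 kPa is
    returned exactly.
    """
    t = np.asarray(t_air_C, dtype=float)
    return 0.61121 * np.exp((18.678 - t / 234.5) * (t / (257.14 + t)))


def vapor_pressure_deficit(spfh, pres, t_air_C):
    """VPD in kPa from specific humidity (kg kg-1), pressure (Pa) and
    air temperature (degC).

    Actual vapor pressure is recovered from the humidity mixing relation
    e = q * (p/1000) / (0.622 + 0.378 q) with p in Pa giving e in kPa.
    Supersaturated inputs would yield a negative deficit; the result is
    floored at 0 since VPD is physically non-negative.
    """
    spfh = np.asarray(spfh, dtype=float)
    pres = np.asarray(pres, dtype=float)
    t_air_C = np.asarray(t_air_C, dtype=float)
    if not (np.all(np.isfinite(spfh)) and np.all(np.isfinite(pres)) and np.all(np.isfinite(t_air_C))):
        raise ValueError("vapor_pressure_deficit requires finite inputs")
    if np.any(pres <= 0):
        raise ValueError("pressure must be positive")
    e_act = spfh * (pres / 1000.0) / (0.622 + spfh * 0.378)
    vpd = vapor_pressure_saturated(t_air_C) - e_act
    out = np.maximum(vpd, 0.0)
    return float(out) if out.ndim == 0 else out


def par_from_shortwave(sw_down, factor=PAR_FACTOR_DEFAULT):
    """PAR (W m-2) as a fixed fraction of downward shortwave (W m-2)."""
    sw = np.asarray(sw_down, dtype=float)
    if np.any(sw < 0):
        raise ValueError("shortwave radiation must be non-negative")
    out = factor * sw
    return float(out) if out.ndim == 0 else out


def clearness_index(sw_down, cos_theta, clip=True):
    """Sky clearness index R = S / (S0 cos(theta)) with S0 = 1367 W m-2.

    ``sw_down`` is the daytime-mean shortwave flux matching the zenith
    cosine supplied.  Clipped to [0, 1] by default to keep the diffuse
    fraction polynomial inside its fitted domain.
    """
    sw = np.asarray(sw_down, dtype=float)
    ct = np.asarray(cos_theta, dtype=float)
    if np.any(ct <= 0):
        raise ValueError("clearness index undefined for cos_theta <= 0 (night)")
    r = sw / (SOLAR_CONSTANT * ct)
    if clip:
        r = np.clip(r, 0.0, 1.0)
    return float(r) if r.ndim == 0 else r


@dataclass
class RawMetStep:
    """One 6-hourly reanalysis record."""

    timestamp: object
    dswrf: float  # J m-2 per 6 h
    spfh: float  # kg kg-1
    tmp: float  # K
    pres: float  # Pa

    def __post_init__(self):
        if self.dswrf < 0:
            raise ValueError("dswrf must be non-negative")
        if not (0.0 <= self.spfh < 0.1):
            raise ValueError("specific humidity out of physical range")
        if not (150.0 < self.tmp < 350.0):
            raise ValueError("temperature out of physical range")
        if not (30000.0 < self.pres < 110000.0):
            raise ValueError("pressure out of physical range")


def daily_from_6hourly(steps):
    """Aggregate exactly four 6-hourly met records to daily values.

    Returns a dict with daily shortwave energy (J m-2 d-1, the sum of the
    four fluxes), its 24-h mean flux (W m-2), and daily means of
    temperature (K) and VPD (kPa).
    """
    steps = list(steps)
    if len(steps) != 4:
        raise ValueError(f"expected exactly 4 six-hourly steps, got {len(steps)}")
    sw_energy = float(sum(s.dswrf for s in steps))
    tmp_mean = float(np.mean([s.tmp for s in steps]))
    vpd_mean = float(
        np.mean([vapor_pressure_deficit(s.spfh, s.pres, s.tmp - 273.15) for s in steps])
    )
    return {
        "sw_energy_J": sw_energy,
        "sw_down": sw_energy / 86400.0,
        "t_air_K": tmp_mean,
        "vpd": vpd_mean,
    }


@dataclass
class DailyForcing:
    """One day of model forcing for a site or pixel."""

    date: object
    t_air_K: float
    vpd: float  # kPa
    sw_down: float  # 24-h mean shortwave, W m-2
    par: float  # 24-h mean PAR, W m-2
    co2_ppm: float
    lai: float
    latitude: float
    doy: int
    cos_theta: float = field(default=None)

    def __post_init__(self):
        if self.cos_theta is None:
            self.cos_theta = solar_cos_zenith(self.latitude, self.doy)


def read_flux_csv(path, latitude=None, par_factor=PAR_FACTOR_DEFAULT):
    """Read a tower daily table into a tidy forcing frame.

    The file is delimited text with FLUXNET2015 FULLSET daily column names:
    TIMESTAMP (YYYYMMDD), TA_F (degC), VPD_F (hPa), CO2_F_MDS (ppm),
    SW_IN_F (W m-2), optionally PPFD_IN, GPP_DT_CUT_MEAN (g C m-2 d-1),
    plus LAI and optionally LATITUDE and SITE_ID.  -9999 marks missing.

    Returns a DataFrame with standardized columns: date, doy, t_air_K,
    vpd (kPa), sw_down, par, co2_ppm, lai, gpp_obs, latitude, site.
    """
    raw = pd.read_csv(path)
    raw = raw.replace(MISSING_SENTINEL, np.nan)
    df = pd.DataFrame()
    df["date"] = pd.to_datetime(raw["TIMESTAMP"], format="%Y%m%d")
    df["doy"] = df["date"].dt.dayofyear
    df["t_air_K"] = raw["TA_F"] + 273.15
    df["vpd"] = raw["VPD_F"] / 10.0  # hPa -> kPa
    df["sw_down"] = raw["SW_IN_F"]
    df["par"] = raw["SW_IN_F"] * par_factor
    df["co2_ppm"] = raw["CO2_F_MDS"]
    df["lai"] = raw["LAI"]
    df["gpp_obs"] = raw.get("GPP_DT_CUT_MEAN")
    if latitude is not None:
        df["latitude"] = latitude
    elif "LATITUDE" in raw:
        df["latitude"] = raw["LATITUDE"]
    else:
        raise ValueError("site latitude required (LATITUDE column or argument)")
    df["site"] = raw["SITE_ID"] if "SITE_ID" in raw else "site"
    return df


def screen_site_years(records, max_missing_days=MAX_MISSING_DAYS_DEFAULT,
                      required=("t_air_K", "vpd", "co2_ppm", "sw_down", "gpp_obs")):
    """Screen site-years by data availability and gap-fill accepted years.

    A site-year is kept only when every required variable has fewer than
    ``max_missing_days`` missing days in that calendar year.  Within
    accepted years, remaining gaps are filled by 1-D linear interpolation
    in time (no extrapolation past the first/last observation).

    Parameters
    ----------
    records : DataFrame with at least date, site and the required columns.

    Returns
    -------
    (filled, report) : the gap-filled frame restricted to accepted
    site-years, and a per-site-year report frame with acceptance flags
    and fill fractions.
    """
    if len(records) == 0:
        return records.copy(), pd.DataFrame(
            columns=["site", "year", "accepted", "fill_fraction"])
    df = records.copy()
    df["_year"] = pd.to_datetime(df["date"]).dt.year
    report_rows = []
    kept = []
    for (site, year), grp in df.groupby(["site", "_year"], sort=True):
        missing = {v: int(grp[v].isna().sum()) for v in required}
        accepted = all(m < max_missing_days for m in missing.values())
        n_missing_total = sum(missing.values())
        fill_fraction = 0.0
        if accepted:
            grp = grp.sort_values("date").copy()
            n_cells = len(grp) * len(required)
            for v in required:
                grp[v] = grp[v].interpolate(method="linear", limit_area="inside")
            fill_fraction = (n_missing_total - sum(int(grp[v].isna().sum()) for v in required)) / max(n_cells, 1)
            kept.append(grp)
        report_rows.append({
            "site": site, "year": int(year), "accepted": accepted,
            "fill_fraction": fill_fraction,
            **{f"missing_{v}": missing[v] for v in required},
        })
    report = pd.DataFrame(report_rows)
    filled = pd.concat(kept, ignore_index=True) if kept else df.iloc[0:0].copy()
    filled = filled.drop(columns=["_year"], errors="ignore")
    return filled, report
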