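"""Two-leaf LUE model core: daily GPP of sunlit and shaded leaves.

    GPP       = GPP_shade + GPP_sun
    GPP_shade = eps_msh * APAR_sh * T_s * W_s * C_s
    GPP_sun   = eps_msu * APAR_su * T_s * W_s * C_s

eps_msh / eps_msu are per-vegetation-type maximum light-use efficiencies
in g C MJ-1, so APAR enters as an energy (MJ m-2 d-1).  Canopy radiation
is partitioned on daytime-mean fluxes (W m-2) and integrated over the
astronomical daylength to obtain that energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .canopy import CanopyGeometry, RadiationPartition, partition_radiation
from .forcing import SOLAR_CONSTANT, clearness_index
from .scalars import ScalarSet, TemperatureLimits, regulation_scalars
from .solar import SECONDS_PER_DAY, daylength_seconds, solar_cos_zenith

PFT_CODES = ("DBF", "EBF", "ENF", "MF", "CRO", "GRA", "OSH", "SAV", "WET", "WSA", "DNF")
#: deciduous needleleaf forests share the deciduous broadleaf parameter set
PFT_ALIASES = {"DNF": "DBF"}


@dataclass
class PftParameters:
    """Calibrated model parameters for one vegetation type."""

    pft_code: str
    eps_msh: float  # g C MJ-1, shaded-leaf maximum LUE
    eps_msu: float  # g C MJ-1, sunlit-leaf maximum LUE
    vpd_max: float  # kPa
    vpd_min: float  # kPa
    t_opt: float  # degC as tabulated
    albedo: float
    clumping: float
    eps_msh_sd: float = np.nan  # across-site spread, metadata only
    eps_msu_sd: float = np.nan

    def __post_init__(self):
        if self.eps_msh <= 0 or self.eps_msu <= 0:
            raise ValueError("maximum LUE values must be positive")

    @property
    def t_opt_K(self) -> float:
        return self.t_opt + 273.15

    @property
    def temperature_limits(self) -> TemperatureLimits:
        return TemperatureLimits(t_opt=self.t_opt_K)


@dataclass
class GppTriple:
    gpp: float  # g C m-2 d-1
    gpp_sun: float
    gpp_shade: float


def load_pft_parameters(path=None) -> dict:
    """Load the per-PFT parameter table (shipped defaults unless a
    delimited-text file with the same columns is given).

    The DNF entry is resolved by aliasing to DBF values.
    """
    if path is None:
        with resources.files("tllue.data").joinpath("pft_parameters.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    params = {}
    for _, row in table.iterrows():
        params[row["pft_code"]] = PftParameters(
            pft_code=row["pft_code"],
            eps_msh=float(row["eps_msh"]), eps_msu=float(row["eps_msu"]),
            vpd_max=float(row["vpd_max"]), vpd_min=float(row["vpd_min"]),
            t_opt=float(row["t_opt"]), albedo=float(row["albedo"]),
            clumping=float(row["clumping"]),
            eps_msh_sd=float(row.get("eps_msh_sd", np.nan)),
            eps_msu_sd=float(row.get("eps_msu_sd", np.nan)),
        )
    for alias, target in PFT_ALIASES.items():
        if alias not in params and target in params:
            src = params[target]
            params[alias] = PftParameters(**{**src.__dict__, "pft_code": alias})
    return params


def get_pft_parameters(pft_code: str, path=None) -> PftParameters:
    params = load_pft_parameters(path)
    if pft_code not in params:
        raise KeyError(f"unknown vegetation type code: {pft_code!r}")
    return params[pft_code]


def gpp_step(forcing, params: PftParameters, return_diagnostics=False,
             co2_units="as-printed"):
    """One daily model step.

    ``forcing`` provides t_air_K, vpd (kPa), sw_down (24-h mean W m-2),
    par (24-h mean W m-2), co2_ppm, lai, latitude and doy (a
    DailyForcing, any object with those attributes, or a mapping).
    Night (zero daylength), zero LAI or zero radiation gives an all-zero
    triple.

    Radiation handling: the 24-h mean fluxes are converted to
    daytime-mean fluxes (energy / daylength), the clearness index and
    canopy partition are evaluated on that basis, and absorbed PAR is
    integrated back over the daylength into MJ m-2 d-1.
    """
    f = forcing if not isinstance(forcing, dict) else type("F", (), forcing)
    lat, doy = f.latitude, f.doy
    cos_theta = getattr(f, "cos_theta", None)
    if cos_theta is None:
        cos_theta = solar_cos_zenith(lat, doy)
    daylen = daylength_seconds(lat, doy)

    zero = GppTriple(0.0, 0.0, 0.0)
    if daylen <= 0 or cos_theta <= 0 or f.lai <= 0 or f.sw_down <= 0:
        if return_diagnostics:
            return zero, None, None
        return zero

    sw_daytime = f.sw_down * SECONDS_PER_DAY / daylen
    par_daytime = f.par * SECONDS_PER_DAY / daylen
    R = clearness_index(sw_daytime, cos_theta)

    geom = CanopyGeometry(lai=f.lai, clumping=params.clumping,
                          albedo=params.albedo, cos_theta=cos_theta)
    rad = partition_radiation(par_daytime, R, geom)
    scal = regulation_scalars(f.t_air_K, f.vpd, f.co2_ppm,
                              params.temperature_limits,
                              params.vpd_min, params.vpd_max, units=co2_units)

    to_mj = daylen * 1e-6  # W m-2 sustained over daylight -> MJ m-2 d-1
    apar_sun_mj = rad.apar_sun * to_mj
    apar_shade_mj = rad.apar_shade * to_mj
    env = scal.t_s * scal.w_s * scal.c_s
    gpp_shade = params.eps_msh * apar_shade_mj * env
    gpp_sun = params.eps_msu * apar_sun_mj * env
    triple = GppTriple(gpp=gpp_shade + gpp_sun, gpp_sun=gpp_sun, gpp_shade=gpp_shade)
    if return_diagnostics:
        return triple, rad, scal
    return triple


def run_series(forcings: pd.DataFrame, params: PftParameters,
               co2_units="as-printed") -> pd.DataFrame:
    """Vectorized daily model run over a time-ordered forcing frame.

    Requires columns date, t_air_K, vpd, sw_down, par, co2_ppm, lai,
    latitude, doy.  Returns a frame with gpp, gpp_sun, gpp_shade plus
    APAR and scalar diagnostics.  Raises if dates are not sorted.
    """
    if len(forcings) == 0:
        return pd.DataFrame(columns=["date", "gpp", "gpp_sun", "gpp_shade"])
    dates = pd.to_datetime(forcings["date"])
    if not dates.is_monotonic_increasing:
        raise ValueError("forcing series must be sorted by date")

    lat = forcings["latitude"].to_numpy(float)
    doy = forcings["doy"].to_numpy(float)
    lai = forcings["lai"].to_numpy(float)
    sw = forcings["sw_down"].to_numpy(float)
    par = forcings["par"].to_numpy(float)

    cos_theta = np.asarray(solar_cos_zenith(lat, doy))
    daylen = np.asarray(daylength_seconds(lat, doy))
    active = (daylen > 0) & (cos_theta > 0) & (lai > 0) & (sw > 0)

    n = len(forcings)
    out = {k: np.zeros(n) for k in
           ("gpp", "gpp_sun", "gpp_shade", "apar_sun_mj", "apar_shade_mj",
            "t_s", "w_s", "c_s", "clearness_R", "lai_sun", "lai_shade")}
    if active.any():
        a = active
        dl = daylen[a]
        sw_day = sw[a] * SECONDS_PER_DAY / dl
        par_day = par[a] * SECONDS_PER_DAY / dl
        ct = cos_theta[a]
        R = np.clip(sw_day / (SOLAR_CONSTANT * ct), 0.0, 1.0)
        geom = CanopyGeometry(lai=lai[a], clumping=params.clumping,
                              albedo=params.albedo, cos_theta=ct)
        rad = partition_radiation(par_day, R, geom)
        scal = regulation_scalars(
            forcings["t_air_K"].to_numpy(float)[a],
            forcings["vpd"].to_numpy(float)[a],
            forcings["co2_ppm"].to_numpy(float)[a],
            params.temperature_limits, params.vpd_min, params.vpd_max,
            units=co2_units)
        to_mj = dl * 1e-6
        apar_su = rad.apar_sun * to_mj
        apar_sh = rad.apar_shade * to_mj
        env = np.asarray(scal.t_s) * np.asarray(scal.w_s) * np.asarray(scal.c_s)
        out["apar_sun_mj"][a] = apar_su
        out["apar_shade_mj"][a] = apar_sh
        out["gpp_sun"][a] = params.eps_msu * apar_su * env
        out["gpp_shade"][a] = params.eps_msh * apar_sh * env
        out["gpp"][a] = out["gpp_sun"][a] + out["gpp_shade"][a]
        out["t_s"][a] = scal.t_s
        out["w_s"][a] = scal.w_s
        out["c_s"][a] = scal.c_s
        out["clearness_R"][a] = R
        out["lai_sun"][a] = rad.lai_sun
        out["lai_shade"][a] = rad.lai_shade
    result = pd.DataFrame({"date": dates.to_numpy(), **out})
    return result
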