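"""Environmental regulation scalars: temperature, water (VPD) and CO2.

Each scalar multiplies the light-use-efficiency term and lies in [0, 1].

* T_s is a rational peak function of air temperature with fixed
  photosynthesis limits (0 and 40 degC) and a per-vegetation-type
  optimum.
* W_s is a linear ramp in vapor pressure deficit between VPD_min
  (no stress) and VPD_max (full stomatal closure).
* C_s follows a Farquhar-style formulation: intercellular CO2 from the
  least-cost optimal ratio chi(VPD, T), a temperature-dependent CO2
  compensation point Gamma*, and Michaelis-Menten coefficients of
  Rubisco for CO2 and O2.

The CO2 chain is implemented exactly as the published coefficient set
prints it, with C_i carried in ppm against compensation-point and
Michaelis constants whose magnitudes match Pa-scale literature values;
an optional ``units='pa'`` mode converts C_i to partial pressure at
standard surface pressure for a dimensionally homogeneous variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAS_CONSTANT = 8.314  # J mol-1 K-1
T_REF = 298.15  # K
O2_PARTIAL_PRESSURE = 21.0  # kPa
ETA_STAR = 0.8903  # viscosity of water relative to 25 degC
T_MIN_DEFAULT = 273.15  # K
T_MAX_DEFAULT = 313.15  # K
XI_CONSTANT = 356.51
PA_PER_PPM = 0.101325  # 1 ppm of a 101325 Pa atmosphere, in Pa


@dataclass
class TemperatureLimits:
    t_opt: float  # K
    t_min: float = T_MIN_DEFAULT
    t_max: float = T_MAX_DEFAULT

    def __post_init__(self):
        if not (self.t_min < self.t_opt < self.t_max):
            raise ValueError("require t_min < t_opt < t_max")


@dataclass
class Co2Intermediates:
    gamma_star: float
    c_i: float
    chi: float
    xi: float
    K: float
    k_c: float
    k_o: float


@dataclass
class ScalarSet:
    t_s: float
    w_s: float
    c_s: float
    co2_detail: Co2Intermediates


def temperature_scalar(t_air_K, limits: TemperatureLimits):
    """T_s = (T-Tmax)(T-Tmin) / [(T-Tmax)(T-Tmin) - (T-Topt)^2].

    Equals 1 at the optimum and 0 at both limits; outside (Tmin, Tmax)
    the rational form leaves [0, 1], so 0 is returned there (no
    photosynthesis beyond the thermal limits).
    """
    t = np.asarray(t_air_K, dtype=float)
    num = (t - limits.t_max) * (t - limits.t_min)
    den = num - (t - limits.t_opt) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        ts = np.where(den != 0.0, num / den, 0.0)
    ts = np.where((t <= limits.t_min) | (t >= limits.t_max), 0.0, ts)
    out = np.clip(ts, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def water_scalar(vpd, vpd_min, vpd_max):
    """W_s = (VPD_max - VPD) / (VPD_max - VPD_min), clamped to [0, 1]."""
    if not vpd_min < vpd_max:
        raise ValueError("require vpd_min < vpd_max")
    v = np.asarray(vpd, dtype=float)
    ws = (vpd_max - v) / (vpd_max - vpd_min)
    out = np.clip(ws, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _arrhenius(t_air_K, coeff, activation):
    t = np.asarray(t_air_K, dtype=float)
    return coeff * np.exp(activation * (t - T_REF) / (T_REF * GAS_CONSTANT * t))


def gamma_star(t_air_K):
    """CO2 compensation point without dark respiration; 4.22 at 25 degC."""
    out = _arrhenius(t_air_K, 4.22, 37830.0)
    return float(out) if np.ndim(out) == 0 else out


def michaelis_coefficients(t_air_K):
    """Rubisco Michaelis-Menten coefficients (k_c, k_o) and the combined
    K = k_c (1 + P_o / k_o) with P_o = 21 kPa.

    At 25 degC the exponentials are exactly 1, giving k_c = 39.97 and
    k_o = 27480.
    """
    k_c = _arrhenius(t_air_K, 39.97, 79.43)
    k_o = _arrhenius(t_air_K, 27480.0, 36.38)
    K = k_c * (1.0 + O2_PARTIAL_PRESSURE / k_o)
    if np.ndim(K) == 0:
        return float(k_c), float(k_o), float(K)
    return k_c, k_o, K


def chi_ratio(vpd, t_air_K):
    """Least-cost optimal ratio of intercellular to ambient CO2.

    xi = sqrt(356.51 K / (1.6 eta*)); chi = xi / (xi + sqrt(VPD)),
    with VPD in kPa.  chi -> 1 as VPD -> 0 and decreases monotonically
    with VPD.  Returns (chi, xi, k_c, k_o, K).
    """
    v = np.asarray(vpd, dtype=float)
    if np.any(v < 0):
        raise ValueError("VPD must be non-negative")
    k_c, k_o, K = michaelis_coefficients(t_air_K)
    xi = np.sqrt(XI_CONSTANT * K / (1.6 * ETA_STAR))
    chi = xi / (xi + np.sqrt(v))
    return chi, xi, k_c, k_o, K


def co2_scalar(c_a_ppm, vpd, t_air_K, units="as-printed"):
    """CO2 regulation scalar C_s = (C_i - Gamma*) / (C_i + 2 Gamma*).

    C_i = chi * C_a.  Floored at 0 when C_i <= Gamma* (no assimilation
    below the compensation point); approaches 1 from below as C_a grows.

    ``units='as-printed'`` (default) evaluates the published coefficient
    set with C_i in ppm; ``units='pa'`` converts C_i to Pa at standard
    surface pressure before combining with Gamma*.
    """
    c_a = np.asarray(c_a_ppm, dtype=float)
    if np.any(c_a <= 0):
        raise ValueError("ambient CO2 must be positive")
    chi, xi, k_c, k_o, K = chi_ratio(vpd, t_air_K)
    g_star = gamma_star(t_air_K)
    c_i = c_a * chi
    c_i_eff = c_i * PA_PER_PPM if units == "pa" else c_i
    c_s = (c_i_eff - g_star) / (c_i_eff + 2.0 * g_star)
    c_s = np.maximum(c_s, 0.0)
    detail = Co2Intermediates(
        gamma_star=g_star if np.ndim(g_star) else float(g_star),
        c_i=c_i if np.ndim(c_i) else float(c_i),
        chi=chi if np.ndim(chi) else float(chi),
        xi=xi if np.ndim(xi) else float(xi),
        K=K, k_c=k_c, k_o=k_o,
    )
    c_s = float(c_s) if np.ndim(c_s) == 0 else c_s
    return c_s, detail


def regulation_scalars(t_air_K, vpd, c_a_ppm, limits: TemperatureLimits,
                       vpd_min, vpd_max, units="as-printed") -> ScalarSet:
    """All three scalars for one forcing step (scalars or aligned arrays)."""
    t_s = temperature_scalar(t_air_K, limits)
    w_s = water_scalar(vpd, vpd_min, vpd_max)
    c_s, detail = co2_scalar(c_a_ppm, vpd, t_air_K, units=units)
    return ScalarSet(t_s=t_s, w_s=w_s, c_s=c_s, co2_detail=detail)
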