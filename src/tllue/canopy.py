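"""Two-leaf canopy radiation partitioning.

Splits above-canopy PAR into direct and diffuse streams via a quartic
clearness-index polynomial, divides the canopy into sunlit and shaded
leaf area with a clumping-adjusted beam-penetration expression, and
computes the PAR absorbed by each fraction, including a multiple-
scattering term and diffuse transmission through the canopy.

All radiation fields are fluxes in W m-2; the caller decides the time
basis (the GPP core uses daytime-mean fluxes and integrates over the
daylength to obtain MJ m-2 d-1 for the light-use-efficiency product).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: quartic diffuse-fraction polynomial coefficients, constant term first
DIFFUSE_POLY = (0.7527, 3.8453, -16.316, 18.962, -7.0802)


@dataclass
class CanopyGeometry:
    """Static canopy optical/structural description for one vegetation type."""

    lai: float  # m2 m-2
    clumping: float  # Omega, 0 < Omega <= 1
    albedo: float
    cos_theta: float
    leaf_angle_deg: float = 60.0

    def __post_init__(self):
        lai = np.asarray(self.lai)
        if np.any(lai < 0):
            raise ValueError("LAI must be non-negative")
        if not (0.0 < self.clumping <= 1.0):
            raise ValueError("clumping index must lie in (0, 1]")
        if not (0.0 <= self.albedo < 1.0):
            raise ValueError("albedo must lie in [0, 1)")


@dataclass
class RadiationPartition:
    """Per-step canopy radiation decomposition."""

    par: float
    par_dif: float
    par_dir: float
    par_dif_u: float
    scatter_C: float
    lai_sun: float
    lai_shade: float
    apar_sun: float
    apar_shade: float
    clearness_R: float
    cos_theta_bar: float


def diffuse_fraction(clearness_R):
    """Fraction of PAR that is diffuse, as a quartic in the clearness index.

    Evaluates 0.7527 + 3.8453 R - 16.316 R^2 + 18.962 R^3 - 7.0802 R^4,
    clipped to [0, 1].  At R = 0 (fully overcast) the fraction is the
    intercept 0.7527; at R = 1 it is 0.1638.
    """
    r = np.asarray(clearness_R, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("clearness index must lie in [0, 1]")
    frac = np.polynomial.polynomial.polyval(r, DIFFUSE_POLY)
    out = np.clip(frac, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def split_par(par, clearness_R):
    """Split total PAR into (diffuse, direct) components; both >= 0 and
    summing exactly to ``par``."""
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be non-negative")
    par_dif = par * diffuse_fraction(clearness_R)
    par_dir = par - par_dif
    if par.ndim == 0:
        return float(par_dif), float(par_dir)
    return par_dif, par_dir


def sunlit_shaded_lai(lai, clumping, cos_theta):
    """Partition LAI into sunlit and shaded leaf area.

    lai_sun = 2 cos(theta) (1 - exp(-LAI Omega / (2 cos(theta)))),
    capped at LAI so lai_shade = LAI - lai_sun is never negative (the
    uncapped expression can marginally exceed LAI at small LAI).
    """
    lai = np.asarray(lai, dtype=float)
    ct = np.asarray(cos_theta, dtype=float)
    if np.any(ct <= 0):
        raise ValueError("sunlit fraction undefined for cos_theta <= 0 (night)")
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    lai_sun = 2.0 * ct * (1.0 - np.exp(-lai * clumping / (2.0 * ct)))
    lai_sun = np.minimum(lai_sun, lai)
    lai_shade = lai - lai_sun
    if lai.ndim == 0 and np.ndim(lai_sun) == 0:
        return float(lai_sun), float(lai_shade)
    return lai_sun, lai_shade


def multiple_scatter(lai, clumping, cos_theta, par_dir):
    """Multiple-scattered radiation C = 0.07 Omega PAR_dir (1.1 - 0.1 LAI) e^(-cos theta).

    The linear LAI term crosses zero at LAI = 11; the result is floored
    at 0 since scattered radiation cannot be negative.
    """
    par_dir = np.asarray(par_dir, dtype=float)
    c = 0.07 * clumping * par_dir * (1.1 - 0.1 * np.asarray(lai, dtype=float)) * np.exp(
        -np.asarray(cos_theta, dtype=float))
    out = np.maximum(c, 0.0)
    return float(out) if out.ndim == 0 else out


def under_canopy_diffuse(lai, clumping, par_dif):
    """Diffuse PAR transmitted below the canopy and the representative
    zenith cosine used for diffuse transmission.

    cos(theta_bar) = 0.537 + 0.025 LAI;
    PAR_dif,u = PAR_dif exp(-0.5 Omega LAI / cos(theta_bar)).
    """
    lai = np.asarray(lai, dtype=float)
    cos_theta_bar = 0.537 + 0.025 * lai
    par_dif_u = np.asarray(par_dif, dtype=float) * np.exp(
        -0.5 * clumping * lai / cos_theta_bar)
    if lai.ndim == 0 and np.ndim(par_dif_u) == 0:
        return float(par_dif_u), float(cos_theta_bar)
    return par_dif_u, cos_theta_bar


def partition_radiation(par, clearness_R, geometry: CanopyGeometry) -> RadiationPartition:
    """Full per-step canopy radiation decomposition.

    ``par`` is the above-canopy PAR flux (W m-2) on whatever time basis
    the caller uses consistently; ``clearness_R`` the matching sky
    clearness.  Accepts scalars or aligned numpy arrays.

    Absorbed PAR per fraction:
        APAR_sh = (1-albedo) ((PAR_dif - PAR_dif,u)/LAI + C) LAI_sh
        APAR_su = (1-albedo) (PAR_dir cos(beta)/cos(theta)
                              + (PAR_dif - PAR_dif,u)/LAI + C) LAI_su
    At LAI = 0 both are defined as 0 (no leaves to absorb), bypassing
    the 0/0 in the per-LAI diffuse term.
    """
    lai = np.asarray(geometry.lai, dtype=float)
    ct = np.asarray(geometry.cos_theta, dtype=float)
    par = np.asarray(par, dtype=float)

    par_dif, par_dir = split_par(par, clearness_R)
    lai_sun, lai_shade = sunlit_shaded_lai(lai, geometry.clumping, ct)
    scatter_c = multiple_scatter(lai, geometry.clumping, ct, par_dir)
    par_dif_u, cos_theta_bar = under_canopy_diffuse(lai, geometry.clumping, par_dif)

    cos_beta = np.cos(np.deg2rad(geometry.leaf_angle_deg))
    one_m_alb = 1.0 - geometry.albedo
    with np.errstate(invalid="ignore", divide="ignore"):
        dif_per_lai = np.where(lai > 0, (par_dif - par_dif_u) / np.where(lai > 0, lai, 1.0), 0.0)
    apar_shade = one_m_alb * (dif_per_lai + scatter_c) * lai_shade
    apar_sun = one_m_alb * (par_dir * cos_beta / ct + dif_per_lai + scatter_c) * lai_sun
    apar_shade = np.maximum(apar_shade, 0.0)
    apar_sun = np.maximum(apar_sun, 0.0)

    def _s(x):
        x = np.asarray(x)
        return float(x) if x.ndim == 0 else x

    return RadiationPartition(
        par=_s(par), par_dif=_s(par_dif), par_dir=_s(par_dir),
        par_dif_u=_s(par_dif_u), scatter_C=_s(scatter_c),
        lai_sun=_s(lai_sun), lai_shade=_s(lai_shade),
        apar_sun=_s(apar_sun), apar_shade=_s(apar_shade),
        clearness_R=_s(np.asarray(clearness_R, dtype=float)),
        cos_theta_bar=_s(cos_theta_bar),
    )
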