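"""Daily solar geometry: declination, daytime-mean zenith cosine, daylength.

The model runs at a daily time step, so a single representative solar
position per day is required.  We use the daytime mean of cos(theta)
obtained analytically by averaging over the sunlit hour-angle range
[-h0, h0], which is exact for the standard solar-position formula:

    cos(theta) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(h)

    <cos(theta)>_day = sin(phi) sin(delta) + cos(phi) cos(delta) sin(h0)/h0

Declination follows the Cooper approximation.  Polar night yields a
daylength (and mean cosine) of exactly 0.
"""

from __future__ import annotations

import numpy as np

SECONDS_PER_DAY = 86400.0


def solar_declination(doy):
    """Solar declination angle in radians for a day of year (Cooper's formula)."""
    doy = np.asarray(doy, dtype=float)
    return np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)


def _sunset_hour_angle(latitude, doy):
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    dec = solar_declination(doy)
    cos_h0 = -np.tan(lat) * np.tan(dec)
    # cos_h0 > 1: polar night (h0 = 0); cos_h0 < -1: midnight sun (h0 = pi)
    return np.arccos(np.clip(cos_h0, -1.0, 1.0)), lat, dec


def solar_cos_zenith(latitude, doy):
    """Daytime-mean cosine of the solar zenith angle.

    Parameters
    ----------
    latitude : float or array, degrees in [-90, 90]
    doy : int or array, day of year in [1, 366]

    Returns
    -------
    Mean of cos(theta) over the sunlit portion of the day; 0 during
    polar night.
    """
    latitude = np.asarray(latitude, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if np.any(~np.isfinite(latitude)) or np.any(np.abs(latitude) > 90.0):
        raise ValueError("latitude must be finite and within [-90, 90] degrees")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day of year must be within [1, 366]")
    h0, lat, dec = _sunset_hour_angle(latitude, doy)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cos = np.sin(lat) * np.sin(dec) + np.cos(lat) * np.cos(dec) * np.divide(
            np.sin(h0), h0, out=np.ones_like(h0), where=h0 > 0
        )
    mean_cos = np.where(h0 <= 0.0, 0.0, np.clip(mean_cos, 0.0, 1.0))
    if mean_cos.ndim == 0:
        return float(mean_cos)
    return mean_cos


def daylength_seconds(latitude, doy):
    """Length of the sunlit period in seconds (0 during polar night)."""
    h0, _, _ = _sunset_hour_angle(latitude, doy)
    out = h0 / np.pi * SECONDS_PER_DAY
    if np.ndim(out) == 0:
        return float(out)
    return out
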