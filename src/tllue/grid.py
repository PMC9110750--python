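"""Gridded GPP products: land-cover remapping, regridding, temporal
aggregation, GeoTIFF encoding and per-pixel trend analysis.

Rasters are xarray DataArrays on regular pixel-center lat/lon grids
(lat descending from north).  Products are written as single-band
GeoTIFFs with the archive conventions: 8-day and monthly fields stored
as 16-bit integers with scale factors 0.01 and 0.1 respectively,
annual fields as doubles; file names <Var>_v21_<period>.tif.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
import tifffile

INT16_NODATA = -32768
SCALE_FACTORS = {"8day": 0.01, "monthly": 0.1, "annual": None}

#: IGBP integer codes used on rasters
IGBP_CODES = {
    1: "ENF", 2: "EBF", 3: "DNF", 4: "DBF", 5: "MF",
    6: "CSH", 7: "OSH", 8: "WSA", 9: "SAV", 10: "GRA",
    11: "WET", 12: "CRO", 13: "URB", 14: "CVM", 15: "ICE",
    16: "BAR", 17: "WAT",
}
#: IGBP classes carrying a model parameter set (CSH borrows OSH, crop
#: mosaic borrows CRO)
IGBP_TO_PFT = {
    1: "ENF", 2: "EBF", 3: "DNF", 4: "DBF", 5: "MF", 6: "OSH", 7: "OSH",
    8: "WSA", 9: "SAV", 10: "GRA", 11: "WET", 12: "CRO", 14: "CRO",
}
IGBP_NODATA = 0

#: default UN-LCCS (ESA-CCI land cover) -> IGBP crosswalk; config-overridable
LCCS_TO_IGBP = {
    10: 12, 11: 12, 12: 12, 20: 12,          # cropland
    30: 14, 40: 14,                          # cropland/natural mosaics
    50: 2,                                   # broadleaf evergreen forest
    60: 4, 61: 4, 62: 4,                     # broadleaf deciduous forest
    70: 1, 71: 1, 72: 1,                     # needleleaf evergreen forest
    80: 3, 81: 3, 82: 3,                     # needleleaf deciduous forest
    90: 5,                                   # mixed forest
    100: 8, 110: 8,                          # tree/shrub & herbaceous mosaics
    120: 7, 121: 7, 122: 7,                  # shrubland
    130: 10, 140: 10,                        # grassland, lichens/mosses
    150: 16, 151: 16, 152: 16, 153: 16,      # sparse vegetation
    160: 11, 170: 11, 180: 11,               # flooded forest / wetland
    190: 13, 200: 16, 201: 16, 202: 16,      # urban, bare
    210: 17, 220: 15,                        # water, snow/ice
}


@dataclass
class GridSpec:
    """Regular pixel-center lat/lon grid."""

    resolution: float = 0.05
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0

    @property
    def lons(self):
        r = self.resolution
        return np.arange(self.lon_min + r / 2, self.lon_max, r)

    @property
    def lats(self):
        r = self.resolution
        return np.arange(self.lat_max - r / 2, self.lat_min, -r)


@dataclass
class ProductSpec:
    variable: str  # GPP | Shade_GPP | Sun_GPP
    cadence: str  # 8day | monthly | annual
    scale_factor: float = field(init=False)
    nodata: float = field(init=False)

    def __post_init__(self):
        if self.cadence not in SCALE_FACTORS:
            raise ValueError(f"unknown cadence {self.cadence!r}")
        self.scale_factor = SCALE_FACTORS[self.cadence]
        self.nodata = INT16_NODATA if self.scale_factor else np.nan


def remap_landcover(lccs_codes, table=None):
    """Map a raster of UN-LCCS class codes to IGBP codes.

    Unknown codes and non-vegetated classes keep their IGBP identity;
    codes absent from the table become nodata (0).
    """
    table = LCCS_TO_IGBP if table is None else table
    codes = np.asarray(lccs_codes)
    out = np.full(codes.shape, IGBP_NODATA, dtype=np.int16)
    for lccs, igbp in table.items():
        out[codes == lccs] = igbp
    if isinstance(lccs_codes, xr.DataArray):
        return lccs_codes.copy(data=out)
    return out


def igbp_to_pft(igbp_codes):
    """IGBP raster -> object array of PFT codes (None where non-vegetated)."""
    codes = np.asarray(igbp_codes)
    out = np.full(codes.shape, None, dtype=object)
    for igbp, pft in IGBP_TO_PFT.items():
        out[codes == igbp] = pft
    return out


def resample_nearest(da: xr.DataArray, target: GridSpec) -> xr.DataArray:
    """Nearest-neighbour regridding onto the target pixel-center grid.

    Categorical values are preserved exactly (pure index selection, no
    arithmetic).
    """
    if "lat" not in da.dims or "lon" not in da.dims:
        raise ValueError("raster must carry 'lat' and 'lon' dimensions")
    return da.sel(lat=xr.DataArray(target.lats, dims="lat"),
                  lon=xr.DataArray(target.lons, dims="lon"),
                  method="nearest").assign_coords(lat=target.lats, lon=target.lons)


def interpolate_lai_daily(lai: xr.DataArray, dates) -> xr.DataArray:
    """Per-pixel linear interpolation of a time-stamped LAI stack onto
    daily dates; endpoints held constant outside the stamped range."""
    if "time" not in lai.dims:
        raise ValueError("LAI stack must carry a 'time' dimension")
    lai = lai.sortby("time")
    dates = pd.DatetimeIndex(dates)
    if lai.sizes["time"] == 1:
        return lai.squeeze("time", drop=True).expand_dims(time=dates)
    out = lai.interp(time=dates, method="linear", kwargs={"fill_value": None})
    first, last = lai.isel(time=0), lai.isel(time=-1)
    out = out.where(out.time >= lai.time[0], first)
    out = out.where(out.time <= lai.time[-1], last)
    return out


def eight_day_period_start(doy):
    """Start DOY of the MODIS-style 8-day period containing ``doy``
    (periods begin at DOY 1, 9, 17, ...)."""
    doy = np.asarray(doy)
    return (doy - 1) // 8 * 8 + 1


def aggregate_products(daily: xr.DataArray, cadence: str) -> xr.DataArray:
    """Aggregate a daily (time, lat, lon) GPP stack to period sums.

    8-day sums follow the MODIS day-of-year grid restarting each year
    (final period short); monthly and annual are calendar sums.  Units
    are g C m-2 per period.  Incomplete trailing periods are still
    summed; the caller flags partials via the returned period lengths.
    """
    if cadence == "8day":
        time = pd.DatetimeIndex(daily["time"].values)
        key = time.year * 1000 + eight_day_period_start(time.dayofyear)
        group = xr.DataArray(np.asarray(key), coords={"time": daily["time"]},
                             dims="time", name="period")
        return daily.groupby(group).sum("time")
    if cadence == "monthly":
        return daily.resample(time="1MS").sum("time")
    if cadence == "annual":
        return daily.resample(time="1YS").sum("time")
    raise ValueError(f"unknown cadence {cadence!r}")


def encode_int16(values, scale_factor, nodata=INT16_NODATA):
    """Quantize to int16 storage: divide by the scale factor and round
    half away from zero.  Raises on int16 overflow, naming a pixel."""
    v = np.asarray(values, dtype=float)
    scaled = v / scale_factor
    rounded = np.copysign(np.floor(np.abs(scaled) + 0.5), scaled)
    finite = np.isfinite(rounded)
    over = finite & (np.abs(rounded) > 32767)
    if over.any():
        ij = tuple(int(k) for k in np.argwhere(over)[0])
        raise OverflowError(f"value {v[over][0]:g} overflows int16 at pixel {ij} "
                            f"with scale factor {scale_factor}")
    out = np.where(finite, rounded, nodata).astype(np.int16)
    return out


def decode_int16(stored, scale_factor, nodata=INT16_NODATA):
    s = np.asarray(stored)
    out = s.astype(float) * scale_factor
    return np.where(s == nodata, np.nan, out)


def product_filename(variable, cadence, year, period=None):
    """Archive naming: GPP_v21_1999.tif (annual),
    Sun_GPP_v21_1999_01.tif (monthly), Shade_GPP_v21_1999_249.tif (8-day)."""
    if cadence == "annual":
        return f"{variable}_v21_{year}.tif"
    if cadence == "monthly":
        return f"{variable}_v21_{year}_{period:02d}.tif"
    if cadence == "8day":
        return f"{variable}_v21_{year}_{period:03d}.tif"
    raise ValueError(f"unknown cadence {cadence!r}")


def _geotiff_tags(lats, lons):
    res_lon = float(abs(lons[1] - lons[0])) if len(lons) > 1 else 0.0
    res_lat = float(abs(lats[1] - lats[0])) if len(lats) > 1 else res_lon
    # tiepoint at the outer corner of the top-left pixel (PixelIsArea)
    west = float(lons[0]) - res_lon / 2
    north = float(lats[0]) + res_lat / 2
    scale = (33550, 'd', 3, (res_lon, res_lat, 0.0), True)
    tiepoint = (33922, 'd', 6, (0.0, 0.0, 0.0, west, north, 0.0), True)
    # minimal GeoKeyDirectory: geographic CRS, EPSG:4326
    keys = (1, 1, 0, 3,
            1024, 0, 1, 2,      # GTModelType: geographic
            1025, 0, 1, 1,      # GTRasterType: PixelIsArea
            2048, 0, 1, 4326)   # GeographicType: WGS 84
    geokeys = (34735, 'H', len(keys), keys, True)
    return [scale, tiepoint, geokeys]


def write_product(raster: xr.DataArray, spec: ProductSpec, year, period,
                  out_dir) -> Path:
    """Write one product raster as a georeferenced single-band GeoTIFF
    with the archive's encoding and naming."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = product_filename(spec.variable, spec.cadence, year, period)
    path = out_dir / name
    lats = np.asarray(raster["lat"].values)
    lons = np.asarray(raster["lon"].values)
    tags = _geotiff_tags(lats, lons)
    data = raster.transpose("lat", "lon").values
    if spec.scale_factor:
        stored = encode_int16(data, spec.scale_factor)
        tags.append((42112, 's', 0, f"{INT16_NODATA}", True))
    else:
        stored = np.asarray(data, dtype=np.float64)
    tifffile.imwrite(path, stored, extratags=tags,
                     metadata=None, photometric="minisblack")
    return path


def read_product(path, spec: ProductSpec = None) -> xr.DataArray:
    """Read a product GeoTIFF back into a DataArray (decoded to g C m-2
    per period when a spec with a scale factor is given)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        scale = page.tags[33550].value
        tiept = page.tags[33922].value
    res_lon, res_lat = float(scale[0]), float(scale[1])
    west, north = float(tiept[3]), float(tiept[4])
    ny, nx = data.shape
    lons = west + res_lon / 2 + np.arange(nx) * res_lon
    lats = north - res_lat / 2 - np.arange(ny) * res_lat
    if spec is not None and spec.scale_factor:
        data = decode_int16(data, spec.scale_factor)
    return xr.DataArray(data, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"))


def write_manifest(paths, out_path):
    """Checksum manifest (JSON) for a set of product files."""
    entries = {}
    for p in sorted(Path(q) for q in paths):
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    out_path = Path(out_path)
    out_path.write_text(json.dumps(entries, indent=1))
    return out_path


def pixel_trend(annual: xr.DataArray, alpha=0.05):
    """Per-pixel OLS trend of annual GPP on year with a two-sided t-test.

    Returns (slope, p_value, mask) DataArrays; the mask retains pixels
    with p <= alpha.  Requires at least 3 annual values.  Constant
    series get slope 0 and are masked out.
    """
    if "time" in annual.dims:
        years = pd.DatetimeIndex(annual["time"].values).year.to_numpy(float)
        stack = annual.rename({"time": "year"}).assign_coords(year=years)
    else:
        stack = annual
        years = np.asarray(stack["year"].values, dtype=float)
    n = len(years)
    if n < 3:
        raise ValueError("trend requires at least 3 annual values per pixel")
    y = stack.transpose("year", "lat", "lon").values.astype(float)
    t = years - years.mean()
    sxx = np.sum(t ** 2)
    slope = np.tensordot(t, y, axes=(0, 0)) / sxx
    resid = y - y.mean(axis=0) - slope[None] * t[:, None, None]
    dof = n - 2
    se2 = np.sum(resid ** 2, axis=0) / dof / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = slope / np.sqrt(se2)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
    # exact-fit pixels: zero residual with nonzero slope is certain trend;
    # constant series (zero slope, zero residual) carry no evidence
    exact = se2 == 0.0
    pval = np.where(np.isfinite(tstat), pval,
                    np.where(exact & (slope != 0.0), 0.0, 1.0))
    coords = {"lat": stack["lat"].values, "lon": stack["lon"].values}
    slope_da = xr.DataArray(slope, coords=coords, dims=("lat", "lon"))
    pval_da = xr.DataArray(pval, coords=coords, dims=("lat", "lon"))
    mask_da = xr.DataArray(pval <= alpha, coords=coords, dims=("lat", "lon"))
    return slope_da, pval_da, mask_da
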