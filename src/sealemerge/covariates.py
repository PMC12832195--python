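"""Environmental covariates for the emergence transition model.

Builds the candidate predictors of daily emergence probability: astronomical
daylength, thawing degree days (days since 1 April with mean temperature
>= 0 degC), a trailing 7-day mean temperature, melt-progression indices
(observation DOY minus satellite melt-onset DOY), and nearest-cell extraction
of gridded products (air temperature, sea-ice concentration, melt onset) at
the seals' daily locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "daylength",
    "thawing_degree_days",
    "rolling_mean_temp",
    "melt_index",
    "CovariateGrid",
    "extract_at",
    "annotate_series",
]

EARTH_OBLIQUITY_DEG = 23.44


def solar_declination(doy):
    """Approximate solar declination (radians) for a day of year.

    Uses the standard cosine approximation with period 365.25 d; the induced
    daylength error is well under the hour-scale resolution of the data.
    """
    doy = np.asarray(doy, dtype=float)
    return np.deg2rad(-EARTH_OBLIQUITY_DEG) * np.cos(2.0 * np.pi * (doy + 10.0) / 365.25)


def daylength(doy, latitude):
    """Astronomical day length in hours from DOY and latitude.

    daylength = (24/pi) * arccos(clamp(-tan(phi) tan(delta), -1, 1)); the
    clamp yields 0 h in polar night and 24 h in polar day.
    """
    doy = np.asarray(doy, dtype=float)
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("doy outside [1, 366]")
    delta = solar_declination(doy)
    x = np.clip(-np.tan(np.deg2rad(lat)) * np.tan(delta), -1.0, 1.0)
    out = (24.0 / np.pi) * np.arccos(x)
    return out if out.ndim else float(out)


def thawing_degree_days(temps: pd.Series) -> pd.Series:
    """Cumulative count of days since 1 April with mean temperature >= 0 degC.

    ``temps`` is indexed by calendar date.  Days before 1 April count 0; the
    counter resets each calendar year.  Missing temperatures contribute 0 to
    the count but do not break the accumulation.
    """
    idx = pd.to_datetime(temps.index)
    vals = temps.to_numpy(dtype=float)
    years = idx.year
    out = np.zeros(len(temps), dtype=float)
    for yr in np.unique(years):
        sel = years == yr
        april1 = pd.Timestamp(year=int(yr), month=4, day=1)
        active = sel & (idx >= april1)
        thaw = np.where(active & ~np.isnan(vals) & (vals >= 0.0), 1.0, 0.0)
        out[sel] = np.cumsum(thaw[sel])
        out[sel & (idx < april1)] = 0.0
    return pd.Series(out, index=temps.index, name="tdd")


def rolling_mean_temp(temps: pd.Series, window: int = 7) -> pd.Series:
    """Trailing mean temperature over the last ``window`` days.

    Partial windows use whatever days are available (min_periods=1): gaps are
    pervasive in tag records and the transition model needs a daily covariate.
    A window with no data at all yields NaN.
    """
    s = pd.Series(temps.to_numpy(dtype=float), index=pd.to_datetime(temps.index))
    return s.rolling(f"{window}D", min_periods=1).mean().set_axis(temps.index).rename("temp_7day")


def melt_index(date, melt_onset_doy):
    """Signed days since melt onset: DOY(date) - melt_onset_doy.

    Negative values mean the haul-out record precedes melt onset (e.g. -5 is
    five days before melt); positive values follow it.
    """
    doy = pd.to_datetime(pd.Series(np.atleast_1d(date))).dt.dayofyear.to_numpy(dtype=float)
    out = doy - np.asarray(melt_onset_doy, dtype=float)
    return out if np.ndim(date) or isinstance(date, (pd.Series, np.ndarray, list)) else float(out[0])


@dataclass
class CovariateGrid:
    """A named regular lat/lon grid, daily or static (melt onset).

    ``data`` is an xarray DataArray with dims ``(lat, lon)`` or
    ``(time, lat, lon)``; coordinates must be monotone.  Missing cells are
    allowed and resolved at extraction time by the nearest valid cell within
    a configurable radius.
    """

    name: str
    data: xr.DataArray

    def __post_init__(self) -> None:
        da = self.data
        for dim in ("lat", "lon"):
            if dim not in da.dims:
                raise ValueError(f"grid {self.name!r} missing dim {dim!r}")
            coord = da[dim].values
            diffs = np.diff(coord)
            if np.all(diffs < 0):  # normalize to ascending
                da = da.sortby(dim)
            elif not np.all(diffs > 0):
                da = da.sortby(dim)
        self.data = da

    @property
    def is_daily(self) -> bool:
        return "time" in self.data.dims

    def value_at(self, lat: float, lon: float, date=None, fill_radius: float = 2.0):
        """Value of the cell containing (lat, lon), nearest-valid-cell filled.

        ``fill_radius`` is in degrees of great-circle-ish distance (lon scaled
        by cos lat); NaN if no valid cell lies within it or the point is
        outside the grid bounding box.
        """
        da = self.data
        if self.is_daily:
            if date is None:
                raise ValueError(f"grid {self.name!r} is daily; a date is required")
            da = da.sel(time=pd.Timestamp(date), method="nearest")
        lats = da["lat"].values
        lons = da["lon"].values
        half_lat = np.median(np.diff(lats)) / 2.0 if len(lats) > 1 else 0.5
        half_lon = np.median(np.diff(lons)) / 2.0 if len(lons) > 1 else 0.5
        if not (lats.min() - half_lat <= lat <= lats.max() + half_lat) or not (
            lons.min() - half_lon <= lon <= lons.max() + half_lon
        ):
            return float("nan")
        v = float(da.sel(lat=lat, lon=lon, method="nearest"))
        if np.isfinite(v):
            return v
        # nearest valid cell within fill_radius (degrees, anisotropy-corrected)
        vals = da.values
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        d2 = (glat - lat) ** 2 + ((glon - lon) * np.cos(np.deg2rad(lat))) ** 2
        d2 = np.where(np.isfinite(vals), d2, np.inf)
        k = np.argmin(d2)
        if np.sqrt(d2.flat[k]) <= fill_radius:
            return float(vals.flat[k])
        return float("nan")


def extract_at(series: pd.DataFrame, grid: CovariateGrid, column: str | None = None,
               fill_radius: float = 2.0) -> pd.DataFrame:
    """Attach a grid variable to a daily series by date and location.

    Uses the grid cell containing each day's (filled) location; masked cells
    fall back to the nearest valid cell within ``fill_radius`` degrees, else
    missing.
    """
    col = column or grid.name
    out = series.copy()
    vals = np.empty(len(series))
    dates = pd.to_datetime(series["date"]) if grid.is_daily else [None] * len(series)
    for i, (la, lo, dt) in enumerate(zip(series["latitude"], series["longitude"], dates)):
        vals[i] = grid.value_at(float(la), float(lo), dt, fill_radius=fill_radius)
    out[col] = vals
    return out


def annotate_series(
    series: pd.DataFrame,
    temp_grid: CovariateGrid | None = None,
    sic_grid: CovariateGrid | None = None,
    melt_early_grid: CovariateGrid | None = None,
    melt_cont_grid: CovariateGrid | None = None,
    fill_radius: float = 2.0,
) -> pd.DataFrame:
    """Build the annotated daily series used by the transition model.

    Adds ``doy``, ``year``, ``daylength`` (deterministic from date/latitude)
    and, where sources are available, ``air_temp``, ``temp_7day``, ``tdd``,
    ``sic``, ``melt_early_index`` and ``melt_cont_index``.  ``air_temp`` may
    already be present as a column (synthetic data) instead of coming from a
    grid.
    """
    out = series.copy()
    dates = pd.to_datetime(out["date"])
    out["doy"] = dates.dt.dayofyear.astype(float)
    out["year"] = dates.dt.year.astype(float)
    out["daylength"] = daylength(out["doy"].to_numpy(), out["latitude"].to_numpy())

    if temp_grid is not None:
        out = extract_at(out, temp_grid, column="air_temp", fill_radius=fill_radius)
    if sic_grid is not None:
        out = extract_at(out, sic_grid, column="sic", fill_radius=fill_radius)
    if melt_early_grid is not None:
        out = extract_at(out, melt_early_grid, column="melt_early_onset", fill_radius=fill_radius)
        out["melt_early_index"] = melt_index(dates, out["melt_early_onset"].to_numpy())
    if melt_cont_grid is not None:
        out = extract_at(out, melt_cont_grid, column="melt_cont_onset", fill_radius=fill_radius)
        out["melt_cont_index"] = melt_index(dates, out["melt_cont_onset"].to_numpy())

    if "air_temp" in out:
        pieces = []
        for _, grp in out.groupby("seal_year_id", sort=False):
            t = pd.Series(grp["air_temp"].to_numpy(), index=pd.to_datetime(grp["date"]))
            grp = grp.copy()
            grp["temp_7day"] = rolling_mean_temp(t).to_numpy()
            grp["tdd"] = thawing_degree_days(t).to_numpy()
            pieces.append(grp)
        out = pd.concat(pieces, ignore_index=True)
    return out
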