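"""Preprocessing of hourly wet/dry telemetry into daily haul-out observations.

Satellite tags on ringed seals report, for every hour, the percent of the hour
the tag was dry.  Dry readings arise both from true haul-out and from brief
surfacing (especially for head-mounted tags), so the raw percent-dry timeline
is first filtered to an "hourly percent hauled out" series, then summarized
into two daily variables:

* ``prop_ho`` — proportion of the day hauled out (sum of hourly percents / 24),
  defined only for days with a complete 24-hour record;
* ``peak_hr`` — weighted circular mean of the solar hour of haul-out, in
  radians on [-pi, pi) with solar noon at 0, undefined when the seal spent
  0% or 100% of the day hauled out.

Daily location estimates are averaged inverse-weighted by the Argos error
radius, and each seal-year is expanded onto a contiguous daily grid with
locations forward-filled (and back-filled at the start of the record).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "apply_haulout_filter",
    "daily_proportion",
    "solar_hour",
    "hour_angle",
    "peak_haulout_hour",
    "average_daily_location",
    "build_daily_series",
]

HOURS_PER_DAY = 24


def _filter_block(values: np.ndarray) -> np.ndarray:
    """Haul-out filter for one contiguous run of hourly percent-dry values.

    An hour is kept if it is >= 50% dry, or if it is < 50% dry but a
    chronological neighbour (within this contiguous run) is >= 95% dry.
    All other hours are set to 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return v
    keep = v >= 50.0
    hot = v >= 95.0
    prev_hot = np.concatenate(([False], hot[:-1]))
    next_hot = np.concatenate((hot[1:], [False]))
    keep |= (v < 50.0) & (prev_hot | next_hot)
    out = np.where(keep, v, 0.0)
    return out


def apply_haulout_filter(hourly, percent_col: str = "percent_dry"):
    """Convert hourly percent-dry values to hourly percent hauled out.

    Parameters
    ----------
    hourly
        Either a 1-D array-like of percent-dry values for one contiguous
        hourly record, or a DataFrame with columns ``seal_year_id``,
        ``timestamp`` (hourly UTC) and *percent_col*.  In the DataFrame case
        adjacency is evaluated only within contiguous hourly runs: an hour on
        the far side of a transmission gap does not count as a neighbour.

    Returns
    -------
    Same shape as the input; DataFrames gain a ``percent_ho`` column.
    """
    if not isinstance(hourly, pd.DataFrame):
        return _filter_block(np.asarray(hourly, dtype=float))

    df = hourly.copy()
    if df.empty:
        df["percent_ho"] = pd.Series(dtype=float)
        return df
    bad = (df[percent_col] < 0) | (df[percent_col] > 100)
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"percent_dry outside [0, 100] at rows {rows}")
    out = np.empty(len(df), dtype=float)
    order = np.arange(len(df))
    for _, grp in df.groupby("seal_year_id", sort=False):
        ts = pd.to_datetime(grp["timestamp"])
        if not ts.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing per seal-year")
        gap = ts.diff() != pd.Timedelta(hours=1)
        gap.iloc[0] = True
        block = gap.cumsum()
        vals = grp[percent_col].to_numpy(dtype=float)
        pos = order[df.index.get_indexer(grp.index)]
        for _, bidx in pd.Series(range(len(grp)), index=grp.index).groupby(block.values):
            sl = bidx.to_numpy()
            out[pos[sl]] = _filter_block(vals[sl])
    df["percent_ho"] = out
    return df


def daily_proportion(percents) -> float:
    """Proportion of the day hauled out from one calendar day's hourly percents.

    Requires a full 24-hour record; otherwise returns NaN (days with partial
    coverage are excluded from analysis rather than extrapolated).
    """
    v = np.asarray(percents, dtype=float)
    if v.size != HOURS_PER_DAY or np.isnan(v).any():
        return float("nan")
    return float(v.sum() / 100.0 / HOURS_PER_DAY)


def solar_hour(utc_hour, longitude):
    """Mean local solar time: ``(utc_hour + longitude / 15) mod 24``.

    The equation of time (±15 min) is ignored; it is small relative to the
    1-hour resolution of the timelines.
    """
    return np.mod(np.asarray(utc_hour, dtype=float) + np.asarray(longitude, dtype=float) / 15.0, 24.0)


def hour_angle(solar_hr):
    """Map a solar hour to radians on [-pi, pi) with solar noon (12:00) at 0."""
    theta = 2.0 * np.pi * (np.asarray(solar_hr, dtype=float) - 12.0) / 24.0
    return np.mod(theta + np.pi, 2.0 * np.pi) - np.pi


def peak_haulout_hour(percents, longitude: float, utc_hours=None) -> float:
    """Weighted circular mean solar hour of haul-out for one day, in radians.

    Each hour is represented by its midpoint (h + 0.5) converted to solar time
    and then to an angle with solar noon at 0 rad; the weight is the hourly
    percent hauled out.  Returns NaN when the seal hauled out 0% or 100% of
    the day, or when the weighted resultant has zero length (antipodal tie).
    """
    v = np.asarray(percents, dtype=float)
    if v.size != HOURS_PER_DAY or np.isnan(v).any():
        return float("nan")
    prop = v.sum() / 100.0 / HOURS_PER_DAY
    if prop <= 0.0 or prop >= 1.0:
        return float("nan")
    if utc_hours is None:
        utc_hours = np.arange(HOURS_PER_DAY, dtype=float)
    theta = hour_angle(solar_hour(np.asarray(utc_hours, dtype=float) + 0.5, longitude))
    s = float(np.sum(v * np.sin(theta)))
    c = float(np.sum(v * np.cos(theta)))
    r = np.hypot(s, c)
    if r < 1e-9 * v.sum():
        return float("nan")
    ang = float(np.arctan2(s, c))
    if ang >= np.pi:  # keep the half-open convention
        ang -= 2.0 * np.pi
    return ang


def average_daily_location(fixes: pd.DataFrame) -> pd.Series:
    """Error-weighted daily mean location from one day's Argos fixes.

    Weights are 1 / error_radius (weight 1 where the radius is missing).
    Longitude is averaged on the circle (vector mean) so records straddling
    the antimeridian average correctly.
    """
    if len(fixes) == 0:
        raise ValueError("average_daily_location requires at least one fix")
    lat = fixes["latitude"].to_numpy(dtype=float)
    lon = fixes["longitude"].to_numpy(dtype=float)
    if "error_radius" in fixes:
        r = fixes["error_radius"].to_numpy(dtype=float)
        w = np.where(np.isnan(r) | (r <= 0), 1.0, 1.0 / np.where(r > 0, r, 1.0))
    else:
        w = np.ones(len(fixes))
    w = w / w.sum()
    lam = np.deg2rad(lon)
    mean_lon = np.rad2deg(np.arctan2(np.sum(w * np.sin(lam)), np.sum(w * np.cos(lam))))
    if mean_lon <= -180.0:
        mean_lon += 360.0
    return pd.Series(
        {
            "latitude": float(np.sum(w * lat)),
            "longitude": float(mean_lon),
            "n_fixes": int(len(fixes)),
            "mean_error_weight": float(np.mean(w)),
        }
    )


def _daily_obs(grp: pd.DataFrame) -> pd.DataFrame:
    """Summarize one seal-year's filtered hourly record into daily variables."""
    ts = pd.to_datetime(grp["timestamp"])
    day = ts.dt.normalize()
    hour = ts.dt.hour.to_numpy()
    rows = []
    for d, sub in grp.assign(_day=day, _hour=hour).groupby("_day"):
        v = np.full(HOURS_PER_DAY, np.nan)
        v[sub["_hour"].to_numpy()] = sub["percent_ho"].to_numpy(dtype=float)
        lon = float(sub["longitude"].iloc[0]) if "longitude" in sub else np.nan
        if np.isnan(v).any():
            rows.append((d, np.nan, np.nan))
        else:
            rows.append((d, daily_proportion(v), peak_haulout_hour(v, lon)))
    return pd.DataFrame(rows, columns=["date", "prop_ho", "peak_hr"])


def build_daily_series(
    hourly: pd.DataFrame,
    locations: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble contiguous per-seal-year daily series with filled locations.

    Parameters
    ----------
    hourly
        Filtered hourly records (output of :func:`apply_haulout_filter`),
        columns ``seal_year_id``, ``timestamp``, ``percent_ho``.
    locations
        Location fixes: ``seal_year_id``, ``date``, ``latitude``,
        ``longitude`` and optionally ``error_radius``; multiple fixes per day
        are combined with :func:`average_daily_location`.
    metadata
        Optional per-seal-year table with ``seal_year_id``, ``age_class``,
        ``sex``.

    The output has one row per seal-year per calendar day from the first to
    the last transmission; inserted days carry missing observations (no
    interpolation).  Locations are forward-filled, with leading gaps filled
    from the first available location of the year.
    """
    hourly = hourly.copy()
    loc_daily = (
        locations.assign(date=pd.to_datetime(locations["date"]).dt.normalize())
        .groupby(["seal_year_id", "date"])
        .apply(average_daily_location, include_groups=False)
        .reset_index()
    )
    # longitude is needed for the solar conversion; attach provisional daily
    # locations to the hourly records first (forward/back-filled per day).
    out = []
    for sid, grp in hourly.groupby("seal_year_id", sort=False):
        locs = loc_daily[loc_daily["seal_year_id"] == sid].set_index("date").sort_index()
        if locs.empty:
            raise ValueError(f"seal-year {sid!r} has no location fixes and no fallback")
        ts = pd.to_datetime(grp["timestamp"])
        start, end = ts.min().normalize(), ts.max().normalize()
        idx = pd.date_range(start, end, freq="D")
        loc_full = locs.reindex(idx).ffill().bfill()
        grp = grp.copy()
        grp["longitude"] = loc_full["longitude"].reindex(ts.dt.normalize()).to_numpy()
        daily = _daily_obs(grp).set_index("date").reindex(idx)
        daily.index.name = "date"
        daily["latitude"] = loc_full["latitude"].to_numpy()
        daily["longitude"] = loc_full["longitude"].to_numpy()
        daily["n_fixes"] = loc_full["n_fixes"].fillna(0).to_numpy()
        daily = daily.reset_index()
        daily.insert(0, "seal_year_id", sid)
        out.append(daily)
    res = pd.concat(out, ignore_index=True)
    if metadata is not None:
        res = res.merge(
            metadata[[c for c in ("seal_year_id", "age_class", "sex") if c in metadata]],
            on="seal_year_id",
            how="left",
        )
    return res
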