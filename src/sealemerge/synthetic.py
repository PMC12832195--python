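"""Synthetic tag records from the emergence model's own generative assumptions.

Simulates a population of tagged ringed seals: a stationary home-range
location per seal-year, a seasonal air-temperature ramp (logistic rise from a
winter to a spring mean plus iid daily noise), deterministic daylength, a
monotone latent state path (lair -> emerged, absorbing) whose daily
transition probability is logit-linear in the covariates, state-dependent
daily observations (ZOIB proportion hauled out, von Mises peak hour), and
contiguous transmission gaps with geometric lengths.  Hourly percent-dry
timelines can be rendered from the daily observations so that the
preprocessing stage can be exercised end to end.

Default parameter values describe an adult-like population: lair-state seals
haul out ~19% of the day at night with weak diel concentration, emerged seals
~55% around solar noon, and emergence probability is near zero below -10 degC
or 10 h of daylength, rising steeply past 0 degC / 15 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .covariates import daylength
from .hmm import EMERGED, LAIR, HMMParams, HMMSpec, design_matrix

__all__ = ["SimConfig", "SimOutput", "adult_like_params", "simulate_covariates",
           "simulate_states", "simulate_observations", "render_hourly", "simulate"]


def adult_like_params() -> HMMParams:
    """Generative truth matching adult field estimates.

    Lair: pi0 = 0.35, interior Beta(1.2, 3.0) (overall mean ~0.19),
    mu = +2.8 rad (~22:48 solar), kappa = 0.5.  Emerged: pi0 = 0.02,
    pi1 = 0.05, Beta(2.7, 2.3) (overall mean ~0.55), mu = -0.05 rad
    (~11:48 solar), kappa = 5.  Transition (raw covariate scale, formula
    air_temp + daylength): logit p = -13.5 + 0.35 T + 0.65 L.
    """
    return HMMParams(
        pi0=np.array([0.35, 0.02]),
        pi1=np.array([0.01, 0.05]),
        a=np.array([1.2, 2.7]),
        b=np.array([3.0, 2.3]),
        mu=np.array([2.8, -0.05]),
        kappa=np.array([0.5, 5.0]),
        beta=np.array([-13.5, 0.35, 0.65]),
        delta=0.01,
    )


@dataclass
class SimConfig:
    """Stated world for the simulation.

    Temperature follows winter_mean + (spring_mean - winter_mean) *
    logistic((doy - ramp_midpoint) / ramp_width) + N(0, daily_noise_sd).
    Transmission gaps start each day with probability ``p_gap_start`` and
    have geometric lengths with the given mean ("gaps of up to 2 weeks were
    common").  One location per seal-year, latitude uniform in
    ``latitude_range``.
    """

    n_seals: int = 40
    start: str = "2015-02-01"
    end: str = "2015-06-30"
    latitude_range: tuple[float, float] = (66.0, 72.0)
    longitude_range: tuple[float, float] = (-170.0, -140.0)
    formula: str = "air_temp+daylength"
    true_params: HMMParams = field(default_factory=adult_like_params)
    winter_mean: float = -20.0
    spring_mean: float = 5.0
    ramp_midpoint: float = 135.0
    ramp_width: float = 12.0
    daily_noise_sd: float = 3.0
    p_gap_start: float = 0.02
    gap_mean_days: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seals < 1:
            raise ValueError("n_seals must be >= 1")
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if (end - start).days < 1:
            raise ValueError("date range must span at least 2 days")
        lo, hi = self.latitude_range
        if not (50.0 <= lo <= hi <= 85.0):
            raise ValueError("latitude_range must lie within [50, 85]")

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def rng(self, stream: int) -> np.random.Generator:
        # independent substreams per stage, all derived from the master seed
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(stream + 1)[stream])


@dataclass
class SimOutput:
    """Simulated daily series plus the generative truth."""

    daily_series: pd.DataFrame
    true_states: pd.DataFrame  # seal_year_id, date, state label
    true_emergence: pd.DataFrame  # seal_year_id, emergence_date (NaT if never)


def simulate_covariates(config: SimConfig) -> pd.DataFrame:
    """Per-seal-day covariates: air temperature ramp, daylength, DOY, location."""
    dates = config.dates()
    rng = config.rng(0)
    lat = rng.uniform(*config.latitude_range, size=config.n_seals)
    lon = rng.uniform(*config.longitude_range, size=config.n_seals)
    frames = []
    doy = dates.dayofyear.to_numpy(dtype=float)
    for i in range(config.n_seals):
        ramp = config.winter_mean + (config.spring_mean - config.winter_mean) * special.expit(
            (doy - config.ramp_midpoint) / config.ramp_width
        )
        noise = rng.normal(0.0, config.daily_noise_sd, size=len(dates)) if config.daily_noise_sd > 0 else 0.0
        frames.append(
            pd.DataFrame(
                {
                    "seal_year_id": f"sim{i:03d}_{dates[0].year}",
                    "date": dates,
                    "doy": doy,
                    "year": float(dates[0].year),
                    "latitude": lat[i],
                    "longitude": lon[i],
                    "air_temp": ramp + noise,
                    "daylength": daylength(doy, lat[i]),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_states(covariates: pd.DataFrame, true_params: HMMParams, seed: int,
                    formula: str = "air_temp+daylength") -> pd.DataFrame:
    """Draw the monotone latent state path for every seal-year.

    Day 1 is emerged with probability delta; on each later day a lair seal
    emerges with probability logistic(beta . x_t), where x_t is that day's
    covariate row (raw scale).  The emerged state is absorbing.
    """
    if covariates[["air_temp", "daylength"]].isna().any().any():
        raise ValueError("covariate table must be complete")
    rng = np.random.default_rng(seed)
    spec = HMMSpec(formula=formula)
    frames = []
    for sid, grp in covariates.groupby("seal_year_id", sort=False):
        X = design_matrix(grp, spec)
        p = special.expit(X @ true_params.beta)
        T = len(grp)
        u = rng.random(T)
        states = np.empty(T, dtype=int)
        states[0] = EMERGED if u[0] < true_params.delta else LAIR
        for t in range(1, T):
            if states[t - 1] == EMERGED:
                states[t] = EMERGED
            else:
                states[t] = EMERGED if u[t] < p[t] else LAIR
        frames.append(pd.DataFrame({"seal_year_id": sid, "date": grp["date"].to_numpy(),
                                    "state": np.where(states == EMERGED, "emerged", "lair")}))
    return pd.concat(frames, ignore_index=True)


def simulate_observations(covariates: pd.DataFrame, states: pd.DataFrame,
                          true_params: HMMParams, seed: int,
                          p_gap_start: float = 0.02, gap_mean_days: float = 4.0) -> pd.DataFrame:
    """Daily observations from the state-dependent distributions, with gaps.

    Proportion hauled out is ZOIB per the day's state; peak hour is von Mises
    and set missing whenever the drawn proportion is exactly 0 or 1 (the tag
    convention).  Whole-day transmission gaps then blank both observations in
    contiguous geometric-length blocks; covariates and locations stay intact.
    """
    rng = np.random.default_rng(seed)
    df = covariates.merge(states, on=["seal_year_id", "date"])
    frames = []
    for sid, grp in df.groupby("seal_year_id", sort=False):
        T = len(grp)
        s = (grp["state"] == "emerged").to_numpy().astype(int)
        u = rng.random(T)
        prop = np.empty(T)
        for st in (LAIR, EMERGED):
            idx = s == st
            n = int(idx.sum())
            if n == 0:
                continue
            pi0, pi1 = true_params.pi0[st], true_params.pi1[st]
            draw = stats.beta.rvs(true_params.a[st], true_params.b[st], size=n, random_state=rng)
            uu = u[idx]
            prop[idx] = np.where(uu < pi0, 0.0, np.where(uu < pi0 + pi1, 1.0, draw))
        peak = np.array(
            [stats.vonmises.rvs(true_params.kappa[st], loc=true_params.mu[st], random_state=rng)
             for st in s]
        )
        peak = np.mod(peak + np.pi, 2 * np.pi) - np.pi
        peak[(prop == 0.0) | (prop == 1.0)] = np.nan
        # contiguous transmission gaps
        missing = np.zeros(T, dtype=bool)
        if p_gap_start > 0:
            t = 0
            while t < T:
                if rng.random() < p_gap_start:
                    glen = rng.geometric(1.0 / max(gap_mean_days, 1.0))
                    missing[t : t + glen] = True
                    t += glen
                else:
                    t += 1
        out = grp.drop(columns="state").copy()
        out["prop_ho"] = np.where(missing, np.nan, prop)
        out["peak_hr"] = np.where(missing, np.nan, peak)
        out["age_class"] = "adult"
        out["sex"] = "F"
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def simulate(config: SimConfig) -> SimOutput:
    """Run the full generative model under one configuration."""
    cov = simulate_covariates(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(4)
    states = simulate_states(cov, config.true_params, int(seeds[1] % 2**31), config.formula)
    daily = simulate_observations(
        cov, states, config.true_params, int(seeds[2] % 2**31),
        p_gap_start=config.p_gap_start, gap_mean_days=config.gap_mean_days,
    )
    rows = []
    for sid, grp in states.groupby("seal_year_id", sort=False):
        emerged = grp[grp["state"] == "emerged"]
        rows.append({"seal_year_id": sid,
                     "emergence_date": pd.Timestamp(emerged["date"].iloc[0]) if len(emerged) else pd.NaT})
    return SimOutput(daily_series=daily, true_states=states,
                     true_emergence=pd.DataFrame(rows))


def render_hourly(daily: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Render hourly percent-dry timelines consistent with the daily summary.

    Each day's total haul-out time (prop * 24 h) is packed into a contiguous
    block of 100% hours centred on the hour whose solar midpoint is closest
    to the day's peak angle, with one partial remainder hour at the block
    edge.  The preprocessing round trip then recovers the proportion within
    1/24 and the peak hour within one hour bin.  Days with missing
    observations produce no hourly rows (a transmission gap).
    """
    from .prep import hour_angle, solar_hour

    rows = []
    for _, r in daily.iterrows():
        if not np.isfinite(r["prop_ho"]):
            continue
        prop = float(r["prop_ho"])
        date = pd.Timestamp(r["date"])
        lon = float(r["longitude"])
        theta = r["peak_hr"] if np.isfinite(r.get("peak_hr", np.nan)) else 0.0
        percents = np.zeros(24)
        if prop >= 1.0:
            percents[:] = 100.0
        elif prop > 0.0:
            mid_angles = hour_angle(solar_hour(np.arange(24) + 0.5, lon))
            d = np.abs(np.mod(mid_angles - theta + np.pi, 2 * np.pi) - np.pi)
            order = np.argsort(d, kind="stable")
            budget = prop * 2400.0
            for h in order:
                take = min(100.0, budget)
                percents[h] = take
                budget -= take
                if budget <= 0:
                    break
        ts = pd.date_range(date, periods=24, freq="h")
        rows.append(pd.DataFrame({"seal_year_id": r["seal_year_id"], "timestamp": ts,
                                  "percent_dry": percents}))
    if not rows:
        return pd.DataFrame(columns=["seal_year_id", "timestamp", "percent_dry"])
    return pd.concat(rows, ignore_index=True)
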