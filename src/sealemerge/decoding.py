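"""Viterbi decoding and emergence-date extraction.

The fitted two-state chain is monotone (emerged is absorbing), so a decoded
path is fully described by its transition day.  The Viterbi dynamic program
here honours the absorbing row and the February known-state mask, treats
missing observations as emission factor 1, and breaks exact ties toward the
LATER transition (staying in the lair) — a conservative choice for emergence
dating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .hmm import EMERGED, LAIR, FitResult, HMMParams, HMMSpec, _log_emissions, _Packed, fit

log = logging.getLogger(__name__)

__all__ = [
    "DecodedTrack",
    "viterbi",
    "viterbi_all",
    "emergence_dates",
    "state_summaries",
    "leave_one_out",
]

STATE_NAMES = {LAIR: "lair", EMERGED: "emerged"}


@dataclass
class DecodedTrack:
    """One seal-year's most probable state path and derived emergence date."""

    seal_year_id: str
    dates: pd.DatetimeIndex
    states: np.ndarray  # 0 = lair, 1 = emerged
    emergence_date: pd.Timestamp | None
    log_prob: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "seal_year_id": self.seal_year_id,
                "date": self.dates,
                "state": [STATE_NAMES[s] for s in self.states],
            }
        )


def _viterbi_one(
    le: np.ndarray, X: np.ndarray, params: HMMParams
) -> tuple[np.ndarray, float]:
    """Log-space Viterbi for one seal-year.

    le: (T, 2) log emissions (February mask already applied); X: (T, k)
    design rows on the same scale as ``params.beta``.  Ties between staying
    emerged and transitioning now are broken toward transitioning now, and the
    final lair-vs-emerged tie toward lair — together these select the latest
    possible transition among maximizers.
    """
    T = le.shape[0]
    delta = np.clip(params.delta, 1e-300, 1 - 1e-300)
    with np.errstate(divide="ignore"):
        pr = special.expit(X @ params.beta)
        logp = np.log(pr)
        log1mp = np.log1p(-pr)
        v = np.array([np.log(1.0 - delta), np.log(delta)]) + le[0]
    ptr = np.zeros((T, 2), dtype=int)
    for t in range(1, T):
        new = np.empty(2)
        new[LAIR] = v[LAIR] + log1mp[t] + le[t, LAIR]
        stay = v[EMERGED]
        switch = v[LAIR] + logp[t]
        if switch >= stay:  # tie -> transition now (later transition overall)
            ptr[t, EMERGED] = LAIR
            new[EMERGED] = switch + le[t, EMERGED]
        else:
            ptr[t, EMERGED] = EMERGED
            new[EMERGED] = stay + le[t, EMERGED]
        v = new
    states = np.empty(T, dtype=int)
    states[-1] = LAIR if v[LAIR] >= v[EMERGED] else EMERGED  # tie -> lair
    for t in range(T - 1, 0, -1):
        states[t - 1] = ptr[t, states[t]] if states[t] == EMERGED else LAIR
    return states, float(v[states[-1]])


def viterbi(fit_result: FitResult, series: pd.DataFrame) -> DecodedTrack:
    """Most probable state path for one seal-year under a fitted model."""
    tracks = viterbi_all(fit_result, series)
    if len(tracks) != 1:
        raise ValueError("viterbi expects a single seal-year; use viterbi_all")
    return tracks[0]


def viterbi_all(fit_result: FitResult, data: pd.DataFrame) -> list[DecodedTrack]:
    """Decode every seal-year in an annotated series."""
    packed = _Packed(data, fit_result.spec)
    # reuse the fit's standardization so params_std.beta applies
    packed.X = (packed.X - fit_result.std_mean) / fit_result.std_sd
    packed.X[..., 0] = 1.0
    le = _log_emissions(packed, fit_result.params_std)
    tracks = []
    for i, sid in enumerate(packed.ids):
        t_len = int(packed.valid[i].sum())
        states, lp = _viterbi_one(le[i, :t_len], packed.X[i, :t_len], fit_result.params_std)
        dates = pd.DatetimeIndex(
            pd.to_datetime(data.loc[data["seal_year_id"] == sid, "date"]).sort_values()
        )
        emerged_idx = np.flatnonzero(states == EMERGED)
        edate = pd.Timestamp(dates[emerged_idx[0]]) if emerged_idx.size else None
        tracks.append(DecodedTrack(sid, dates, states, edate, lp))
    return tracks


def emergence_dates(
    tracks: list[DecodedTrack], data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-seal emergence dates with covariates at emergence.

    Returns ``(table, diagnostics)``: the table has one row per seal-year
    whose decoded path reached the emerged state (date, DOY, location and any
    available covariates on that date); seal-years that never emerged appear
    in the diagnostics frame with their coverage window.
    """
    keep_cols = [c for c in ("latitude", "longitude", "air_temp", "daylength", "year")
                 if c in data.columns]
    rows, diag = [], []
    for tr in tracks:
        sub = data[data["seal_year_id"] == tr.seal_year_id]
        if tr.emergence_date is None:
            diag.append(
                {
                    "seal_year_id": tr.seal_year_id,
                    "first_date": tr.dates.min(),
                    "last_date": tr.dates.max(),
                    "n_observed": int(sub["prop_ho"].notna().sum()),
                }
            )
            continue
        at = sub[pd.to_datetime(sub["date"]) == tr.emergence_date].iloc[0]
        row = {
            "seal_year_id": tr.seal_year_id,
            "emergence_date": tr.emergence_date,
            "doy": float(tr.emergence_date.dayofyear),
            "year": float(tr.emergence_date.year),
        }
        for c in keep_cols:
            if c != "year":
                row[c] = float(at[c])
        rows.append(row)
    table = pd.DataFrame(rows)
    diagnostics = pd.DataFrame(diag)
    return table, diagnostics


def _circular_mean(theta: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta))))


def _kappa_mle(theta: np.ndarray) -> float:
    """Concentration estimate by inverting the mean resultant length (A1)."""
    r = float(np.hypot(np.mean(np.sin(theta)), np.mean(np.cos(theta))))
    if r < 1e-12:
        return 0.0
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1 / (r**3 - 4 * r**2 + 3 * r)


def state_summaries(tracks: list[DecodedTrack], data: pd.DataFrame) -> pd.DataFrame:
    """Observed behaviour summarized by decoded state.

    Per state: mean and SD of the daily proportion hauled out (percent),
    circular mean peak haul-out hour as solar clock hours, an empirical von
    Mises concentration, and record counts.  Only days with non-missing
    observations contribute.
    """
    assign = pd.concat([t.to_frame() for t in tracks], ignore_index=True)
    assign["date"] = pd.to_datetime(assign["date"])
    df = data.copy()
    df["date"] = pd.to_datetime(df["date"])
    merged = df.merge(assign, on=["seal_year_id", "date"], how="inner")
    rows = []
    for state in ("lair", "emerged"):
        sub = merged[merged["state"] == state]
        props = sub["prop_ho"].dropna().to_numpy(dtype=float)
        peaks = sub["peak_hr"].dropna().to_numpy(dtype=float)
        row = {"state": state, "n_prop": len(props), "n_peak": len(peaks)}
        if len(props):
            row["mean_prop_pct"] = float(100 * props.mean())
            row["sd_prop_pct"] = float(100 * props.std(ddof=1)) if len(props) > 1 else 0.0
        else:
            row["mean_prop_pct"] = np.nan
            row["sd_prop_pct"] = np.nan
            log.warning("no observed records decoded to state %s", state)
        if len(peaks):
            mean_rad = _circular_mean(peaks)
            row["peak_hr_rad"] = mean_rad
            row["peak_solar_hour"] = float((mean_rad * 24 / (2 * np.pi) + 12) % 24)
            row["kappa_hat"] = _kappa_mle(peaks)
        else:
            row["peak_hr_rad"] = np.nan
            row["peak_solar_hour"] = np.nan
            row["kappa_hat"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def leave_one_out(
    spec: HMMSpec,
    data: pd.DataFrame,
    unit_col: str | None = None,
    inits: HMMParams | None = None,
    n_restarts: int = 2,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Leave-one-out sensitivity of Viterbi emergence dates.

    Refits the model with each unit (by default each seal-year; pass a
    ``unit_col`` such as ``seal_id`` to drop both years of a two-year animal
    together) removed, re-decodes the remaining seal-years, and reports the
    per-seal-year SD of emergence DOY across iterations plus the number of
    iterations in which no emergence was found.
    """
    units = data[unit_col] if unit_col else data["seal_year_id"]
    unit_ids = units.unique()
    if len(unit_ids) < 3:
        raise ValueError("leave-one-out needs at least 3 units")
    records: dict[str, list[float]] = {sid: [] for sid in data["seal_year_id"].unique()}
    none_count: dict[str, int] = {sid: 0 for sid in records}
    n_failed = 0
    for held in unit_ids:
        rest = data[units != held]
        try:
            fr = fit(spec, rest, inits=inits, n_restarts=n_restarts, seed=seed,
                     compute_se=False, **fit_kwargs)
        except Exception as exc:  # pragma: no cover
            log.warning("LOO refit failed holding out %s: %s", held, exc)
            n_failed += 1
            continue
        if not fr.converged:
            log.warning("LOO refit non-convergent holding out %s; excluded", held)
            n_failed += 1
            continue
        for tr in viterbi_all(fr, rest):
            if tr.emergence_date is None:
                none_count[tr.seal_year_id] += 1
            else:
                records[tr.seal_year_id].append(float(tr.emergence_date.dayofyear))
    rows = []
    for sid, doys in records.items():
        arr = np.asarray(doys)
        rows.append(
            {
                "seal_year_id": sid,
                "n_iterations": len(arr),
                "sd_days": float(arr.std(ddof=1)) if len(arr) > 1 else (0.0 if len(arr) else np.nan),
                "n_no_emergence": none_count[sid],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_failed_refits"] = n_failed
    out.attrs["n_refits"] = len(unit_ids)
    return out
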