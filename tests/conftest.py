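"""Shared fixtures and independent oracles for the test suite.

The enumeration oracle exploits the monotone structure of the chain: because
the emerged state is absorbing, every admissible state path is "lair until
day tau, emerged from day tau on" (or never emerged), so the likelihood and
the most probable path can be computed by explicit enumeration over the T+1
candidate paths, entirely independently of the forward/Viterbi recursions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

import sealemerge as se


# ---------------------------------------------------------------------------
# enumeration oracle (independent of sealemerge.hmm internals)


def oracle_log_emissions(prop, peak, params, feb):
    """Per-day per-state log emissions computed directly from scipy."""
    T = len(prop)
    le = np.zeros((T, 2))
    for t in range(T):
        for s in range(2):
            v = 0.0
            if np.isfinite(prop[t]):
                x = prop[t]
                if x == 0.0:
                    dens = params.pi0[s]
                elif x == 1.0:
                    dens = params.pi1[s]
                else:
                    dens = (1 - params.pi0[s] - params.pi1[s]) * stats.beta.pdf(
                        x, params.a[s], params.b[s]
                    )
                v += np.log(dens) if dens > 0 else -np.inf
            if np.isfinite(peak[t]):
                v += params.kappa[s] * np.cos(peak[t] - params.mu[s]) - np.log(
                    2 * np.pi * special.i0(params.kappa[s])
                )
            le[t, s] = v
        if feb[t]:
            le[t, 1] = -np.inf
    return le


def oracle_enumerate(prop, peak, x, params, feb):
    """(log-likelihood, best monotone path) by explicit path enumeration.

    ``x`` is the single covariate column; the design row is [1, x_t].  Ties
    in the argmax break toward the LATEST transition, matching the package's
    documented convention.
    """
    T = len(prop)
    le = oracle_log_emissions(prop, peak, params, feb)
    X = np.column_stack([np.ones(T), np.asarray(x, dtype=float)])
    p = special.expit(X @ params.beta)
    with np.errstate(divide="ignore"):
        logp, log1mp = np.log(p), np.log1p(-p)
        logd = np.log(params.delta) if params.delta > 0 else -np.inf
        log1md = np.log1p(-params.delta) if params.delta < 1 else -np.inf
    scores = np.empty(T + 1)  # tau = first emerged index; T = never emerged
    for tau in range(T + 1):
        if tau == 0:
            prior = logd
        elif tau < T:
            prior = log1md + log1mp[1:tau].sum() + logp[tau]
        else:
            prior = log1md + log1mp[1:T].sum()
        scores[tau] = prior + le[:tau, 0].sum() + le[tau:, 1].sum()
    ll = special.logsumexp(scores)
    best_tau = int(np.flatnonzero(scores == scores.max())[-1])  # latest transition
    path = np.zeros(T, dtype=int)
    path[best_tau:] = 1
    return float(ll), path


def random_case(rng, T=None):
    """One random (data, params) draw for the oracle-equivalence checks."""
    T = int(T or rng.integers(1, 9))
    params = se.HMMParams(
        pi0=rng.uniform(0.05, 0.4, 2),
        pi1=rng.uniform(0.02, 0.2, 2),
        a=rng.uniform(0.5, 4, 2),
        b=rng.uniform(0.5, 4, 2),
        mu=rng.uniform(-np.pi, np.pi, 2),
        kappa=rng.uniform(0.1, 8, 2),
        beta=rng.normal(0, 1.5, 2),
        delta=float(rng.uniform(0.01, 0.4)),
    )
    prop = rng.uniform(0, 1, T)
    prop[rng.random(T) < 0.15] = 0.0
    prop[rng.random(T) < 0.1] = 1.0
    prop[rng.random(T) < 0.2] = np.nan
    peak = rng.uniform(-np.pi, np.pi, T)
    peak[(prop == 0) | (prop == 1) | ~np.isfinite(prop)] = np.nan
    peak[rng.random(T) < 0.1] = np.nan
    x = rng.normal(0, 1, T)
    feb = np.zeros(T, dtype=bool)
    if rng.random() < 0.3:
        feb[: rng.integers(1, T + 1)] = True
    return prop, peak, x, params, feb


def case_to_frame(prop, peak, x, feb):
    """Wrap one oracle case as an annotated series the package accepts.

    The February known-state flags are encoded through real calendar dates:
    the flagged prefix gets February days, the rest run into March.  The
    covariate is exposed as the ``air_temp`` column so the single-covariate
    formula "air_temp" applies the coefficient vector to [1, x].
    """
    T = len(prop)
    n_feb = int(feb.sum())
    start = pd.Timestamp("2015-03-01") - pd.Timedelta(days=n_feb)
    return pd.DataFrame(
        {
            "seal_year_id": "case",
            "date": pd.date_range(start, periods=T, freq="D"),
            "prop_ho": prop,
            "peak_hr": peak,
            "air_temp": np.asarray(x, dtype=float),
            "latitude": 70.0,
            "longitude": -150.0,
        }
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by the fit/decoding tests."""
    cfg = se.SimConfig(n_seals=8, start="2015-02-01", end="2015-06-10", seed=11)
    out = se.simulate(cfg)
    ann = se.covariates.annotate_series(out.daily_series)
    return cfg, out, ann


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One converged fit of the true formula on the small dataset."""
    _, _, ann = small_sim
    return se.fit(se.HMMSpec("air_temp+daylength"), ann, n_restarts=1, seed=0)
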