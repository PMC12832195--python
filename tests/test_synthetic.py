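"""The generative model: covariate ramps, latent paths, observations, hourly."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

import sealemerge as se
from sealemerge import prep, synthetic
from sealemerge.synthetic import adult_like_params


class TestSimConfig:
    def test_rejects_bad_ranges(self):
        with pytest.raises(ValueError):
            se.SimConfig(n_seals=0)
        with pytest.raises(ValueError):
            se.SimConfig(start="2015-05-01", end="2015-05-01")
        with pytest.raises(ValueError):
            se.SimConfig(latitude_range=(40.0, 70.0))


class TestSimulateCovariates:
    def test_ramp_asymptote_without_noise(self):
        cfg = se.SimConfig(n_seals=2, start="2015-02-01", end="2015-02-10",
                           daily_noise_sd=0.0, winter_mean=-25.0, spring_mean=5.0,
                           ramp_midpoint=130.0, ramp_width=10.0, seed=0)
        cov = synthetic.simulate_covariates(cfg)
        # DOY 32-41, ~10 ramp widths below the midpoint
        assert np.allclose(cov["air_temp"], -25.0, atol=0.01)

    def test_determinism(self):
        cfg = se.SimConfig(n_seals=3, seed=42)
        a = synthetic.simulate_covariates(cfg)
        b = synthetic.simulate_covariates(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_midpoint_mean_matches_analytic_ramp(self):
        # at the ramp midpoint the expected temperature is the mean of the
        # winter and spring asymptotes: (-25 + 5)/2 = -10
        cfg = se.SimConfig(n_seals=1000, start="2015-05-08", end="2015-05-12",
                           winter_mean=-25.0, spring_mean=5.0, ramp_midpoint=130.0,
                           ramp_width=10.0, daily_noise_sd=2.0, seed=5)
        cov = synthetic.simulate_covariates(cfg)
        at_mid = cov.loc[cov["doy"] == 130, "air_temp"]
        assert len(at_mid) == 1000
        assert at_mid.mean() == pytest.approx(-10.0, abs=3 * 2.0 / np.sqrt(1000))

    def test_rejects_short_range(self):
        with pytest.raises(ValueError, match="at least 2 days"):
            se.SimConfig(n_seals=1, start="2015-05-01", end="2015-05-01")

    def test_daylength_matches_covariates_module(self):
        cfg = se.SimConfig(n_seals=2, seed=3)
        cov = synthetic.simulate_covariates(cfg)
        from sealemerge.covariates import daylength

        expected = daylength(cov["doy"].to_numpy(), cov["latitude"].to_numpy())
        assert np.allclose(cov["daylength"], expected)


class TestSimulateStates:
    def _flat_covariates(self, n_seals, T, seed=0):
        cfg = se.SimConfig(n_seals=n_seals, start="2015-03-01",
                           end=str(pd.Timestamp("2015-03-01") + pd.Timedelta(days=T - 1)),
                           seed=seed)
        return synthetic.simulate_covariates(cfg)

    def _constant_p_params(self, p, delta=0.0):
        tp = adult_like_params()
        beta = np.array([special.logit(p) if 0 < p < 1 else (-50.0 if p == 0 else 50.0), 0.0, 0.0])
        return se.HMMParams(**{**tp.__dict__, "beta": beta, "delta": delta})

    def test_never_emerges_at_minus_inf_intercept(self):
        cov = self._flat_covariates(20, 30)
        states = synthetic.simulate_states(cov, self._constant_p_params(0.0), seed=1)
        assert (states["state"] == "lair").all()

    def test_certain_transition_emerges_day_two(self):
        cov = self._flat_covariates(20, 5)
        states = synthetic.simulate_states(cov, self._constant_p_params(1.0), seed=1)
        for _, grp in states.groupby("seal_year_id"):
            assert grp["state"].tolist() == ["lair"] + ["emerged"] * 4

    def test_geometric_waiting_time(self):
        # constant hazard p = 0.1 from a lair start: waiting time to emergence
        # is geometric with mean 10 days
        cov = self._flat_covariates(5000, 200, seed=9)
        states = synthetic.simulate_states(cov, self._constant_p_params(0.1), seed=2)
        waits = []
        for _, grp in states.groupby("seal_year_id"):
            emerged = np.flatnonzero((grp["state"] == "emerged").to_numpy())
            if emerged.size:
                waits.append(emerged[0])  # days after day 1
        waits = np.asarray(waits, dtype=float)
        assert len(waits) > 4900  # truncation at T=200 is negligible
        assert waits.mean() == pytest.approx(10.0, abs=0.5)

    def test_paths_monotone(self):
        cfg = se.SimConfig(n_seals=30, seed=4)
        out = se.simulate(cfg)
        for _, grp in out.true_states.groupby("seal_year_id"):
            s = (grp["state"] == "emerged").to_numpy().astype(int)
            assert np.all(np.diff(s) >= 0)
        # emergence date equals first emerged day
        for _, row in out.true_emergence.iterrows():
            grp = out.true_states[out.true_states["seal_year_id"] == row["seal_year_id"]]
            emerged = grp[grp["state"] == "emerged"]
            if pd.isna(row["emergence_date"]):
                assert emerged.empty
            else:
                assert pd.Timestamp(emerged["date"].iloc[0]) == row["emergence_date"]


class TestSimulateObservations:
    def test_lair_pi0_one_gives_zero_days(self):
        tp = adult_like_params()
        tp = se.HMMParams(**{**tp.__dict__,
                             "pi0": np.array([1.0, tp.pi0[1]]),
                             "pi1": np.array([0.0, tp.pi1[1]]),
                             "beta": np.array([-50.0, 0.0, 0.0])})
        cfg = se.SimConfig(n_seals=5, start="2015-03-01", end="2015-03-30",
                           true_params=tp, p_gap_start=0.0, seed=6)
        out = se.simulate(cfg)
        assert (out.daily_series["prop_ho"] == 0.0).all()
        assert out.daily_series["peak_hr"].isna().all()

    def test_emerged_circular_mean_consistency(self):
        # kappa = 50 around mu = 0: the sample circular mean of emerged peak
        # hours concentrates tightly at 0
        tp = adult_like_params()
        tp = se.HMMParams(**{**tp.__dict__,
                             "mu": np.array([tp.mu[0], 0.0]),
                             "kappa": np.array([tp.kappa[0], 50.0]),
                             "delta": 1.0})  # start emerged: all days emerged
        cfg = se.SimConfig(n_seals=20, start="2015-03-01", end="2015-06-10",
                           true_params=tp, p_gap_start=0.0, seed=8)
        out = se.simulate(cfg)
        peaks = out.daily_series["peak_hr"].dropna().to_numpy()
        assert len(peaks) >= 1500
        mean_dir = np.arctan2(np.sin(peaks).mean(), np.cos(peaks).mean())
        assert abs(mean_dir) < 0.05

    def test_no_gaps_when_disabled(self):
        cfg = se.SimConfig(n_seals=10, p_gap_start=0.0, seed=3)
        out = se.simulate(cfg)
        assert out.daily_series["prop_ho"].notna().all()
        # peak only missing on all-in or all-out days
        d = out.daily_series
        missing_peak = d["peak_hr"].isna()
        assert (d.loc[missing_peak, "prop_ho"].isin([0.0, 1.0])).all()

    def test_gap_lengths_blank_whole_days(self):
        cfg = se.SimConfig(n_seals=10, p_gap_start=0.05, gap_mean_days=4.0, seed=12)
        out = se.simulate(cfg)
        d = out.daily_series
        gap = d["prop_ho"].isna()
        assert gap.any()
        assert d.loc[gap, "peak_hr"].isna().all()
        assert d.loc[gap, "air_temp"].notna().all()  # covariates stay intact

    def test_full_sim_determinism(self):
        a = se.simulate(se.SimConfig(n_seals=4, seed=77))
        b = se.simulate(se.SimConfig(n_seals=4, seed=77))
        assert a.daily_series.to_csv(index=False) == b.daily_series.to_csv(index=False)
        assert a.true_states.to_csv(index=False) == b.true_states.to_csv(index=False)


class TestRenderHourly:
    def _one_day(self, prop, peak=0.0, lon=-7.5):
        return pd.DataFrame(
            {"seal_year_id": ["s1"], "date": [pd.Timestamp("2015-04-15")],
             "prop_ho": [prop], "peak_hr": [peak], "latitude": [70.0], "longitude": [lon]}
        )

    def test_full_day(self):
        hourly = synthetic.render_hourly(self._one_day(1.0))
        assert (hourly["percent_dry"] == 100.0).all() and len(hourly) == 24

    def test_empty_day(self):
        hourly = synthetic.render_hourly(self._one_day(0.0))
        assert (hourly["percent_dry"] == 0.0).all() and len(hourly) == 24

    def test_round_trip_quarter_day_at_noon(self):
        daily = self._one_day(0.25, peak=0.0)
        hourly = synthetic.render_hourly(daily)
        filtered = prep.apply_haulout_filter(hourly)
        v = filtered["percent_ho"].to_numpy()
        assert prep.daily_proportion(v) == pytest.approx(0.25, abs=1 / 24)
        assert abs(prep.peak_haulout_hour(v, -7.5)) <= 0.27

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_property_on_simulated_days(self, seed):
        cfg = se.SimConfig(n_seals=3, start="2015-04-01", end="2015-05-15",
                           p_gap_start=0.0, seed=seed)
        out = se.simulate(cfg)
        daily = out.daily_series
        hourly = synthetic.render_hourly(daily, seed=seed)
        filtered = prep.apply_haulout_filter(hourly)
        ts = pd.to_datetime(filtered["timestamp"])
        filtered["date"] = ts.dt.normalize()
        for (sid, date), grp in filtered.groupby(["seal_year_id", "date"]):
            row = daily[(daily["seal_year_id"] == sid) & (pd.to_datetime(daily["date"]) == date)].iloc[0]
            v = np.zeros(24)
            v[ts[grp.index].dt.hour.to_numpy()] = grp["percent_ho"].to_numpy()
            assert prep.daily_proportion(v) == pytest.approx(row["prop_ho"], abs=1 / 24 + 1e-9)
            if 0.0 < row["prop_ho"] < 1.0 and np.isfinite(row["peak_hr"]):
                got = prep.peak_haulout_hour(v, row["longitude"])
                if np.isfinite(got):
                    diff = abs((got - row["peak_hr"] + np.pi) % (2 * np.pi) - np.pi)
                    assert diff <= 2 * np.pi / 24 + 1e-9
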