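"""Emission densities, constrained likelihood, fitting and model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

import sealemerge as se
from sealemerge import hmm
from sealemerge.synthetic import adult_like_params

from conftest import case_to_frame, oracle_enumerate, random_case


class TestZoib:
    def test_point_masses(self):
        assert hmm.zoib_density(0.0, 0.3, 0.05, 2, 5) == pytest.approx(0.3)
        assert hmm.zoib_density(1.0, 0.3, 0.05, 2, 5) == pytest.approx(0.05)

    def test_quadrature_normalization(self):
        pi0, pi1, a, b = 0.3, 0.05, 2.0, 5.0
        interior, _ = integrate.quad(lambda x: hmm.zoib_density(x, pi0, pi1, a, b), 0, 1)
        assert pi0 + pi1 + interior == pytest.approx(1.0, abs=1e-8)

    def test_rejects_outside_unit_interval(self):
        with pytest.raises(ValueError):
            hmm.zoib_density(1.5, 0.3, 0.05, 2, 5)


class TestVonMises:
    def test_uniform_limit(self):
        theta = np.linspace(-np.pi, np.pi, 9)
        assert hmm.von_mises_density(theta, 0.7, 0.0) == pytest.approx(1 / (2 * np.pi))

    def test_mode_at_mu(self):
        theta = np.linspace(-np.pi, np.pi, 1441)
        d = hmm.von_mises_density(theta, 0.5, 3.0)
        assert theta[np.argmax(d)] == pytest.approx(0.5, abs=0.01)

    def test_quadrature_normalization(self):
        total, _ = integrate.quad(lambda t: hmm.von_mises_density(t, 0.5, 3.0), -np.pi, np.pi)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_periodicity(self):
        assert hmm.von_mises_density(0.3, 1.0, 2.0) == pytest.approx(
            hmm.von_mises_density(0.3 + 2 * np.pi, 1.0, 2.0)
        )


class TestTransitionMatrix:
    def test_logistic_midpoint(self):
        G = hmm.transition_matrix([0.0], [0.0, 1.0])
        assert G[0, 1] == pytest.approx(0.5)

    def test_emerged_row_absorbing(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            G = hmm.transition_matrix(rng.normal(size=2), rng.normal(size=3))
            assert G[1].tolist() == [0.0, 1.0]
            assert G[0].sum() == pytest.approx(1.0)

    def test_monotone_in_covariate(self):
        beta = [0.2, 0.8]
        ps = [hmm.transition_matrix([x], beta)[0, 1] for x in np.linspace(-5, 5, 11)]
        assert np.all(np.diff(ps) > 0)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError):
            hmm.transition_matrix([np.nan], [0.0, 1.0])


class TestLogLikelihood:
    SPEC = se.HMMSpec("air_temp")

    def test_all_missing_single_day(self):
        df = case_to_frame(np.array([np.nan]), np.array([np.nan]), np.array([0.0]),
                           np.array([False]))
        params = adult_like_params()
        params = se.HMMParams(**{**params.__dict__, "beta": np.array([-2.0, 0.5])})
        assert hmm.log_likelihood(params, df, self.SPEC) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10**9))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        prop, peak, x, params, feb = random_case(rng)
        expected, _ = oracle_enumerate(prop, peak, x, params, feb)
        got = hmm.log_likelihood(params, case_to_frame(prop, peak, x, feb), self.SPEC)
        if np.isfinite(expected):
            assert got == pytest.approx(expected, abs=1e-8)
        else:
            assert got == -np.inf

    def test_february_mask_equals_forced_lair(self):
        # an emerged-looking February day contributes only the lair emission
        rng = np.random.default_rng(3)
        prop, peak, x, params, feb = random_case(rng, T=6)
        prop[:2], peak[:2] = 0.9, -0.02  # strongly emerged-like observations
        feb[:] = False
        feb[:2] = True
        ll_masked = hmm.log_likelihood(params, case_to_frame(prop, peak, x, feb), self.SPEC)
        # hand construction: enumeration restricted to paths that are lair on
        # the masked days is exactly what the mask enforces
        expected, _ = oracle_enumerate(prop, peak, x, params, feb)
        assert ll_masked == pytest.approx(expected, abs=1e-8)

    def test_nonfinite_params_give_neg_inf(self):
        df = case_to_frame(np.array([0.5]), np.array([0.1]), np.array([0.0]), np.array([False]))
        params = adult_like_params()
        bad = se.HMMParams(**{**params.__dict__, "beta": np.array([np.nan, 0.0])})
        assert hmm.log_likelihood(bad, df, self.SPEC) == -np.inf


class TestCountParameters:
    # the full candidate set and its parameter counts (emission 8 + circular 4
    # + initial 1 + transition coefficients)
    EXPECTED = {
        "none": 14,
        "doy": 15,
        "daylength": 15,
        "sic": 15,
        "melt_early": 15,
        "melt_cont": 15,
        "air_temp": 15,
        "temp_7day": 15,
        "tdd": 15,
        "air_temp+daylength": 16,
        "temp_7day+daylength": 16,
        "doy*sex": 17,
        "doy*latitude": 17,
        "daylength*latitude": 17,
        "doy*year": 17,
    }

    def test_candidate_set_is_exactly_fifteen(self):
        assert set(se.CANDIDATE_FORMULAS) == set(self.EXPECTED)

    @pytest.mark.parametrize("formula,k", sorted(EXPECTED.items()))
    def test_counts(self, formula, k):
        assert se.count_parameters(se.HMMSpec(formula)) == k


class TestFit:
    def test_determinism(self, small_sim, small_fit):
        _, _, ann = small_sim
        fit2 = se.fit(small_fit.spec, ann, n_restarts=1, seed=0)
        assert small_fit.converged
        assert fit2.loglik == pytest.approx(small_fit.loglik, abs=1e-9)
        assert np.allclose(fit2.working, small_fit.working)

    def test_aic_identity(self, small_fit):
        assert small_fit.aic == pytest.approx(
            -2 * small_fit.loglik + 2 * small_fit.n_parameters
        )
        assert small_fit.n_parameters == 16

    def test_fit_improves_on_inits(self, small_sim, small_fit):
        _, _, ann = small_sim
        ll_init = None
        # evaluate the initial values through the same packed/standardized path
        packed = hmm._Packed(ann, small_fit.spec)
        packed.standardize()
        ll_init = hmm._forward_loglik(packed, small_fit.inits)
        assert small_fit.loglik >= ll_init

    def test_beta_backtransform_consistency(self, small_sim, small_fit):
        # natural-scale and standardized-scale coefficients give the same
        # linear predictor on the observed rows
        _, _, ann = small_sim
        X = hmm.design_matrix(ann, small_fit.spec)
        Xz = (X - small_fit.std_mean) / small_fit.std_sd
        Xz[:, 0] = 1.0
        eta_nat = X @ small_fit.params.beta
        eta_std = Xz @ small_fit.params_std.beta
        assert np.allclose(eta_nat, eta_std, atol=1e-8)


class TestSelectModels:
    def test_ranking_and_tiebreak(self, small_sim):
        _, _, ann = small_sim
        table = se.select_models(["none", "air_temp+daylength"], ann, n_restarts=1, seed=0)
        assert table.loc[0, "dAIC"] == 0.0
        assert bool(table.loc[0, "best"])
        # the true-covariate model should beat the null decisively here
        assert table.loc[0, "formula"] == "air_temp+daylength"

    def test_null_preferred_under_null_truth(self):
        """When the covariate truly has no effect, AIC should usually keep the
        null model (penalty 2 vs a ~chi2_1/2 likelihood gain)."""
        wins = 0
        n_sim = 8
        for i in range(n_sim):
            cfg = se.SimConfig(
                n_seals=6, start="2015-03-01", end="2015-04-30", seed=100 + i,
                p_gap_start=0.0,
            )
            # constant emergence hazard: zero out the covariate effects
            tp = adult_like_params()
            tp = se.HMMParams(**{**tp.__dict__, "beta": np.array([-3.5, 0.0, 0.0])})
            cfg.true_params = tp
            out = se.simulate(cfg)
            ann = se.covariates.annotate_series(out.daily_series)
            # "sic" is pure noise here: independent of the transition hazard
            rng = np.random.default_rng(i)
            ann["sic"] = rng.uniform(0, 1, len(ann))
            table = se.select_models(["none", "sic"], ann, n_restarts=1, seed=0, maxiter=300)
            if table.loc[0, "formula"] == "none":
                wins += 1
        assert wins >= int(0.6 * n_sim)


class TestEmergenceCurve:
    def test_midpoint_and_ci_shape(self, small_fit):
        fixed = {"daylength": 18.0}
        curve = hmm.emergence_curve(small_fit, "air_temp", np.linspace(-20, 5, 26), fixed)
        assert ((curve["lo"] <= curve["p"]) & (curve["p"] <= curve["hi"])).all()
        assert curve["p"].is_monotonic_increasing  # positive temperature effect

    def test_delta_method_matches_parametric_bootstrap(self, small_fit):
        fixed = {"daylength": 18.0}
        values = np.array([-10.0, -2.0, 2.0])
        curve = hmm.emergence_curve(small_fit, "air_temp", values, fixed)
        # bootstrap: draw working betas from their asymptotic normal
        rng = np.random.default_rng(0)
        cov_beta = small_fit.cov_working[13:, 13:]
        draws = rng.multivariate_normal(small_fit.params_std.beta, cov_beta, size=10_000)
        grid = pd.DataFrame({"air_temp": values, "daylength": fixed["daylength"]})
        X = hmm.design_matrix(grid, small_fit.spec)
        Xz = (X - small_fit.std_mean) / small_fit.std_sd
        Xz[:, 0] = 1.0
        p_draws = special.expit(draws @ Xz.T)
        lo, hi = np.quantile(p_draws, [0.025, 0.975], axis=0)
        assert np.allclose(curve["lo"], lo, atol=0.02)
        assert np.allclose(curve["hi"], hi, atol=0.02)

    def test_extrapolation_flagged(self, small_fit):
        curve = hmm.emergence_curve(small_fit, "air_temp", [-100.0, 0.0], {"daylength": 18.0})
        assert bool(curve.loc[0, "extrapolated"]) and not bool(curve.loc[1, "extrapolated"])
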