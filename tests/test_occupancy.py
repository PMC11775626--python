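"""Occupancy model: likelihood against latent-state enumeration, MLE
closed forms, sampler behaviour and posterior summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit
from scipy.stats import kstest, norm

from occudiel.occupancy import (
    OccupancyModel,
    site_likelihood,
    split_rhat,
    summarize_draws,
)
from tests.conftest import simulate_history


def enumeration_likelihood(y, psi, p, mask=None):
    """Brute-force oracle: sum over the latent state z in {0, 1}."""
    y = np.asarray(y, float)
    mask = np.ones_like(y, bool) if mask is None else np.asarray(mask, bool)
    p = np.broadcast_to(np.asarray(p, float), y.shape)
    total = 0.0
    for z in (0, 1):
        pr_y = 1.0
        for yj, pj, mj in zip(y, p, mask):
            if not mj:
                continue
            pr_det = z * pj
            pr_y *= pr_det if yj else 1.0 - pr_det
        total += (psi if z else 1.0 - psi) * pr_y
    return total


class TestSiteLikelihood:
    @pytest.mark.parametrize("psi, p, y, expected", [
        (0.5, 0.5, [0, 0], 0.625),       # 0.5*0.25 + 0.5
        (1.0, 0.3, [1, 0], 0.21),
    ])
    def test_hand_arithmetic_cases(self, psi, p, y, expected):
        assert site_likelihood(y, psi, p) == pytest.approx(expected, abs=1e-12)

    @given(st.integers(1, 4), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_equals_latent_enumeration(self, J, seed):
        rng = np.random.default_rng(seed)
        psi = rng.uniform(0.01, 0.99)
        p = rng.uniform(0.01, 0.99, size=J)
        y = rng.integers(0, 2, size=J)
        mask = rng.random(J) < 0.8
        y = y * mask
        mine = site_likelihood(y, psi, p, mask)
        oracle = enumeration_likelihood(y, psi, p, mask)
        assert mine == pytest.approx(oracle, abs=1e-12)

    def test_model_loglike_is_sum_of_site_logs(self, rng):
        y, x, _, _ = simulate_history(rng, 30, 4, (0.2, 0.8), -0.3)
        X = np.column_stack([np.ones(30), x])
        m = OccupancyModel(y, psi_design=X)
        params = np.array([0.1, 0.5, -0.2])
        psi = expit(X @ params[:2])
        p = expit(params[2])
        manual = sum(np.log(site_likelihood(y[i], psi[i], p))
                     for i in range(30))
        assert m.loglike(params) == pytest.approx(manual, rel=1e-10)

    def test_design_row_mismatch_rejected(self, rng):
        y = rng.integers(0, 2, size=(10, 3))
        with pytest.raises(ValueError, match="match"):
            OccupancyModel(y, psi_design=np.ones((9, 1)))


class TestMLE:
    def test_naive_proportion_when_p_fixed_at_one(self):
        # 46 detected sites of 94 -> psi-hat = 46/94 under perfect detection
        y = np.zeros((94, 5), dtype=int)
        y[:46, 0] = 1
        m = OccupancyModel(y)
        res = m.fit(fix_p_at=1.0)
        assert expit(res.params.iloc[0]) == pytest.approx(46 / 94, abs=1e-6)

    def test_saturated_data_pushes_estimates_to_boundary(self):
        y = np.ones((20, 6), dtype=int)
        res = OccupancyModel(y).fit()
        assert expit(res.params.iloc[0]) > 0.95
        assert expit(res.params.iloc[1]) > 0.95

    def test_recovery_on_simulated_data(self, rng):
        y, _, _, _ = simulate_history(rng, 500, 14, (logit(0.54),), logit(0.74))
        res = OccupancyModel(y).fit()
        assert res.converged
        assert expit(res.params.iloc[0]) == pytest.approx(0.54, abs=0.03)
        assert expit(res.params.iloc[1]) == pytest.approx(0.74, abs=0.03)

    def test_nonconvergence_is_flagged_not_fatal(self):
        # a site never detected with one occasion: flat ridge, still returns
        y = np.zeros((3, 1), dtype=int)
        res = OccupancyModel(y).fit()
        assert res.params.notna().all()
        assert isinstance(res.converged, bool)


class TestSampler:
    def test_same_seed_identical_chains(self, rng):
        y, x, _, _ = simulate_history(rng, 50, 5, (0.0, 1.0), 0.0)
        X = np.column_stack([np.ones(50), x])
        m = OccupancyModel(y, psi_design=X)
        kw = dict(chains=2, adapt=100, burnin=100, iterations=300, seed=42)
        a = m.sample(**kw)
        b = m.sample(**kw)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_no_data_reproduces_the_prior(self):
        # zero unmasked occasions: the coefficient posterior is the prior
        y = np.zeros((20, 2), dtype=int)
        mask = np.zeros_like(y, dtype=bool)
        m = OccupancyModel(y, mask=mask, prior_sd=2.0)
        res = m.sample(chains=2, adapt=500, burnin=500, iterations=5000, seed=7)
        draws = res.draws["psi_intercept"].ravel()
        stat = kstest(draws[::5], norm(0, 2.0).cdf).statistic
        assert stat < 0.05

    def test_posterior_agrees_with_mle_on_large_data(self, rng):
        y, x, _, _ = simulate_history(rng, 400, 10, (0.3, 1.0), 0.4)
        X = np.column_stack([np.ones(400), x])
        m = OccupancyModel(y, psi_design=X, prior_sd=10.0)
        mle = m.fit()
        post = m.sample(chains=3, adapt=400, burnin=400, iterations=1500,
                        seed=3)
        s = post.summary(derived=False)
        for name in mle.params.index:
            assert abs(s.loc[name, "mean"] - mle.params[name]) \
                < 2.0 * s.loc[name, "sd"]

    def test_convergence_warning_on_rhat_breach(self, rng):
        y, x, _, _ = simulate_history(rng, 40, 4, (0.0, 0.5), 0.0)
        X = np.column_stack([np.ones(40), x])
        m = OccupancyModel(y, psi_design=X)
        with pytest.warns(RuntimeWarning, match="Rhat"):
            m.sample(chains=3, adapt=10, burnin=0, iterations=30, seed=0)


class TestSummaries:
    def test_overlap0_follows_interval_sign(self):
        rng = np.random.default_rng(0)
        # one parameter boxed away from zero, one straddling it
        away = rng.normal(2.3, 1.0, size=(3, 4000)) * 0.5 + 1.2
        straddle = rng.normal(0.6, 1.0, size=(3, 4000))
        s = summarize_draws({"away": away, "straddle": straddle})
        assert s.loc["away", "overlap0"] == 0
        assert s.loc["straddle", "overlap0"] == 1
        assert (s["LCL"] <= s["UCL"]).all()

    def test_iid_chains_have_unit_rhat(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(3, 10_000))
        s = summarize_draws({"x": d})
        assert s.loc["x", "Rhat"] < 1.01
        assert split_rhat(d) < 1.01

    def test_zero_variance_parameter_flagged(self):
        s = summarize_draws({"const": np.ones((3, 100))})
        assert s.loc["const", "Rhat"] == 1.0
        assert s.loc["const", "flag_degenerate"]

    def test_credible_level_is_configurable(self, rng):
        y, x, _, _ = simulate_history(rng, 60, 5, (0.0, 1.0), 0.0)
        X = np.column_stack([np.ones(60), x])
        res = OccupancyModel(y, psi_design=X).sample(
            chains=2, adapt=200, burnin=200, iterations=800, seed=5)
        s95 = res.summary(level=0.95)
        s99 = res.summary(level=0.99)
        assert (s99["LCL"] <= s95["LCL"]).all()
        assert (s99["UCL"] >= s95["UCL"]).all()


class TestPredictPsi:
    def test_zero_coefficients_give_half(self):
        y = np.zeros((5, 2), dtype=int)
        m = OccupancyModel(y)
        draws = {"psi": np.zeros((2, 10, 1)), "p": np.zeros((2, 10, 1))}
        from occudiel.occupancy import OccupancyMCMCResults

        res = OccupancyMCMCResults(model=m, coef_draws=draws, draws={},
                                   seed=0, settings={})
        assert np.allclose(res.predict_psi()["psi_mean"], 0.5)

    def test_monotone_in_positive_covariate(self, rng):
        y, x, _, _ = simulate_history(rng, 100, 8, (0.0, 1.5), 0.5)
        X = np.column_stack([np.ones(100), x])
        res = OccupancyModel(y, psi_design=X).sample(
            chains=2, adapt=300, burnin=300, iterations=1000, seed=2)
        psi = res.predict_psi()["psi_mean"].to_numpy()
        hi, lo = np.argmax(x), np.argmin(x)
        assert psi[hi] > psi[lo]

    def test_matches_per_draw_brute_force(self, rng):
        y, x, _, _ = simulate_history(rng, 5, 3, (0.0, 1.0), 0.0)
        X = np.column_stack([np.ones(5), x])
        m = OccupancyModel(y, psi_design=X)
        res = m.sample(chains=2, adapt=50, burnin=50, iterations=40, seed=9)
        got = res.predict_psi()["psi_mean"].to_numpy()
        b = res.coef_draws["psi"].reshape(-1, 2)
        brute = expit(b @ X.T).mean(axis=0)
        np.testing.assert_allclose(got, brute, rtol=1e-12)
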