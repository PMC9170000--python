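"""Hierarchical spline model: structure, densities, sampler, prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmspline.errors import (ConfigurationError, ExtrapolationError,
                             ModelConstructionError, PredictionError)
from pmspline.logbook import DesignMatrices
from pmspline.model import (ModelSpec, build_model,
                            count_monitored_parameters, fit, predict,
                            spline_basis)
from pmspline.splines import bspline_basis, knot_vector


def _spec(**kw):
    base = dict(chains=2, iterations=400, burn_in=200, seed=7)
    base.update(kw)
    return ModelSpec(**base)


def _tiny_design(n_records=12, n_days=1, seed=0, sigma=0.2, mu0=0.8):
    """Minimal single-category design: pure mean/variance estimation."""
    rng = np.random.default_rng(seed)
    n = n_records * n_days
    day_idx = np.repeat(np.arange(n_days), n_records)
    y = mu0 + rng.normal(0, sigma, n)
    return DesignMatrices(
        y=y,
        X_station=np.zeros((n, 0)), X_environment=np.zeros((n, 0)),
        X_event=np.zeros((n, 0)),
        t=np.tile(np.linspace(0, 360, n_records), n_days),
        day_idx=day_idx, job_idx=np.zeros(n, dtype=int),
        stations=["S1"], environments=["E1"], events=[],
        day_ids=[f"d{i}" for i in range(n_days)], jobs=["station_agent"],
        day_jobs=np.zeros(n_days, dtype=int),
        reference_station="S1", reference_environment="E1",
    )


class TestCountMonitored:
    def test_full_design_counts_117(self):
        spec = _spec(stations=[f"s{i}" for i in range(45)],
                     environments=[f"e{i}" for i in range(8)],
                     events=[f"v{i}" for i in range(10)],
                     day_ids=[f"d{i}" for i in range(24)],
                     jobs=["a", "b", "c"])
        assert count_monitored_parameters(spec) == 117

    def test_minimal_design(self):
        spec = _spec(stations=["s"], environments=["e"], events=[],
                     day_ids=["d"], jobs=["j"])
        assert count_monitored_parameters(spec) == 6

    def test_linear_in_days(self):
        def count(n_days):
            return count_monitored_parameters(_spec(
                stations=["s"], environments=["e"], events=[],
                day_ids=[f"d{i}" for i in range(n_days)], jobs=["j"]))
        assert count(10) - count(4) == 2 * 6

    def test_unbound_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            count_monitored_parameters(_spec())


class TestSplineBasis:
    def test_partition_of_unity_and_nonnegative(self):
        t = np.linspace(0, 360, 113)
        B = bspline_basis(t, 0, 360, 8)
        assert (B >= 0).all()
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_continuity_at_knots(self):
        for knot in np.linspace(0, 360, 10)[1:-1]:
            left = bspline_basis([knot - 1e-9], 0, 360, 8)
            right = bspline_basis([knot + 1e-9], 0, 360, 8)
            np.testing.assert_allclose(left, right, atol=1e-6)

    def test_extrapolation_rejected(self):
        with pytest.raises(ExtrapolationError):
            bspline_basis([-1.0], 0, 360, 8)
        with pytest.raises(ExtrapolationError):
            spline_basis(np.array([0.0, 400.0]), _spec(), hi=360.0)

    def test_matches_cox_de_boor_recursion(self):
        """Independent Cox-de Boor recursion oracle, 100 random points."""
        def cdb(i, k, x, t):
            if k == 0:
                return 1.0 if t[i] <= x < t[i + 1] else 0.0
            out = 0.0
            if t[i + k] > t[i]:
                out += (x - t[i]) / (t[i + k] - t[i]) * cdb(i, k - 1, x, t)
            if t[i + k + 1] > t[i + 1]:
                out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) \
                    * cdb(i + 1, k - 1, x, t)
            return out

        rng = np.random.default_rng(42)
        kv = knot_vector(0.0, 360.0, 8, 3)
        xs = rng.uniform(1e-6, 360.0 - 1e-6, 100)
        B = bspline_basis(xs, 0.0, 360.0, 8)
        oracle = np.array([[cdb(i, 3, x, kv) for i in range(B.shape[1])]
                           for x in xs])
        assert np.max(np.abs(B - oracle)) < 1e-10


class TestDensities:
    def test_loglik_matches_brute_force_normal_sum(self, small_design):
        """Null-effect log-likelihood == per-record Normal density sum."""
        design = small_design
        spec = _spec()
        model = build_model(design, spec)
        n_days = len(design.day_ids)
        rng = np.random.default_rng(1)
        mu = rng.normal(0.5, 0.2, n_days)
        sigma2 = rng.uniform(0.02, 0.08, n_days)
        params = {"alpha": np.zeros(len(design.stations)),
                  "beta": np.zeros(len(design.environments)),
                  "gamma": np.zeros(len(design.events)),
                  "mu_day": mu, "sigma2_day": sigma2}
        oracle = sum(
            stats.norm.logpdf(y, mu[d], np.sqrt(sigma2[d]))
            for y, d in zip(design.y, design.day_idx))
        assert model.log_likelihood(params) == pytest.approx(oracle,
                                                             abs=1e-10)

    def test_record_order_does_not_change_posterior(self, small_dataset):
        from pmspline.logbook import annotate, build_design
        cfg = small_dataset.config
        frames = [annotate(d.mass["PM1"], d.logbook)
                  for d in small_dataset.days]
        rec = pd.concat(frames, ignore_index=True)
        d1 = build_design(rec, cfg.stations[0], cfg.environments[0])
        d2 = build_design(rec.sample(frac=1.0, random_state=3),
                          cfg.stations[0], cfg.environments[0])
        spec = _spec()
        m1, m2 = build_model(d1, spec), build_model(d2, spec)
        rng = np.random.default_rng(0)
        params = {
            "alpha": np.concatenate([[0], rng.normal(0, .05,
                                                     len(d1.stations) - 1)]),
            "beta": np.concatenate([[0], rng.normal(0, .1,
                                                    len(d1.environments) - 1)]),
            "gamma": rng.normal(0, .1, len(d1.events)),
            "mu_day": rng.normal(.5, .2, len(d1.day_ids)),
            "sigma2_day": rng.uniform(.02, .08, len(d1.day_ids)),
            "m_job": rng.normal(.5, .1, len(d1.jobs)),
            "tau2_job": rng.uniform(.02, .05, len(d1.jobs)),
        }
        assert m1.log_posterior(params) == pytest.approx(
            m2.log_posterior(params), abs=1e-8)

    def test_day_unsorted_design_rejected(self):
        dm = _tiny_design(n_days=2)
        dm.day_idx = dm.day_idx[::-1].copy()
        with pytest.raises(ModelConstructionError):
            build_model(dm, _spec())


class TestSampler:
    def test_same_seed_identical_draws(self):
        dm = _tiny_design(n_records=20, n_days=2)
        spec = _spec(iterations=300, burn_in=100, use_trend=False)
        d1 = fit(build_model(dm, spec))
        d2 = fit(build_model(dm, spec))
        np.testing.assert_array_equal(d1.mu_day, d2.mu_day)
        np.testing.assert_array_equal(d1.sigma2_day, d2.sigma2_day)

    def test_single_chain_rejected(self):
        with pytest.raises(ConfigurationError):
            fit(build_model(_tiny_design(), _spec(chains=1)))

    def test_variances_positive_and_reference_zero(self, small_fit):
        _, draws = small_fit
        assert (draws.sigma2_day > 0).all() and (draws.tau2_job > 0).all()
        assert np.all(draws.alpha[:, :, 0] == 0)
        assert np.all(draws.beta[:, :, 0] == 0)
        assert np.isfinite(draws.alpha).all()

    def test_degenerate_design_is_mean_variance_estimation(self):
        """Single day/category: posterior of mu matches the Normal-Normal
        closed form with near-pinned variances."""
        sigma2_true, tau2_pin = 0.04, 0.09
        dm = _tiny_design(n_records=200, seed=5, sigma=np.sqrt(sigma2_true))
        a = 1.0e6
        spec = _spec(iterations=3000, burn_in=500, use_trend=False,
                     var_prior_shape=a, var_prior_rate=(a + 1) * sigma2_true,
                     job_mean_prior_sd=10.0)
        # pin tau2 as well via its shared prior; tau2 ~= sigma2_true here
        draws = fit(build_model(dm, spec))
        assert np.allclose(draws.sigma2_day.mean(), sigma2_true, rtol=0.02)
        n, ybar = len(dm.y), dm.y.mean()
        prior_var = spec.job_mean_prior_sd ** 2 + sigma2_true  # m + day level
        post_mean = (n * ybar / sigma2_true) / (n / sigma2_true + 1 / prior_var)
        mu = draws.mu_day[:, :, 0].reshape(-1)
        se = mu.std() / np.sqrt(len(mu) / 10)  # conservative ESS
        assert abs(mu.mean() - post_mean) < 3 * se + 1e-4

    def test_posterior_matches_ensemble_sampler(self):
        """Gibbs posterior == emcee ensemble sampler on the same density."""
        import emcee

        dm = _tiny_design(n_records=15, seed=3)
        spec = _spec(use_trend=False, iterations=4000, burn_in=1000)
        model = build_model(dm, spec)

        def logpost(x):
            mu, ls2, m, lt2 = x
            p = {"alpha": np.zeros(1), "beta": np.zeros(1),
                 "gamma": np.zeros(0), "mu_day": np.array([mu]),
                 "sigma2_day": np.array([np.exp(ls2)]),
                 "m_job": np.array([m]), "tau2_job": np.array([np.exp(lt2)])}
            return model.log_posterior(p) + ls2 + lt2  # log-scale Jacobians

        rng = np.random.default_rng(0)
        p0 = np.column_stack([
            rng.normal(dm.y.mean(), 0.05, 24),
            np.log(rng.uniform(0.02, 0.08, 24)),
            rng.normal(dm.y.mean(), 0.3, 24),
            np.log(rng.uniform(0.02, 0.3, 24))])
        sampler = emcee.EnsembleSampler(24, 4, logpost)
        sampler.run_mcmc(p0, 4000, progress=False)
        emcee_mu = sampler.get_chain(discard=1500, flat=True)[:, 0]

        draws = fit(model)
        gibbs_mu = draws.mu_day[:, :, 0].reshape(-1)
        tol = 3 * np.sqrt(emcee_mu.var() / 200 + gibbs_mu.var() / 500)
        assert abs(gibbs_mu.mean() - emcee_mu.mean()) < tol
        assert np.isclose(gibbs_mu.std(), emcee_mu.std(), rtol=0.2)


class TestPredict:
    def test_prediction_on_training_design(self, small_fit):
        model, draws = small_fit
        pp = predict(model, draws, model.design)
        assert len(pp) == model.n
        assert (pp["lo_log10"] <= pp["median_log10"]).all()
        assert (pp["median_log10"] <= pp["hi_log10"]).all()
        np.testing.assert_allclose(pp["median"], 10 ** pp["median_log10"])

    def test_interval_width_tracks_day_variance(self, small_fit):
        model, draws = small_fit
        pp = predict(model, draws, model.design)
        width = (pp["hi_log10"] - pp["lo_log10"]).groupby(
            pp["day_id"]).mean()
        fitted_sd = pd.Series(
            np.sqrt(draws.sigma2_day.mean(axis=(0, 1))),
            index=draws.day_ids)
        r = np.corrcoef(width[fitted_sd.index], fitted_sd)[0, 1]
        assert r > 0.9

    def test_unseen_category_rejected(self, small_fit):
        model, draws = small_fit
        bad = dataclasses.replace(model.design,
                                  stations=model.design.stations + ["ghost"])
        with pytest.raises(PredictionError, match="ghost"):
            predict(model, draws, bad)

    def test_noise_free_recovery(self):
        """With tiny residual variance the predictive median hits the truth."""
        from pmspline.simulate import SimConfig, generate_dataset
        from tests_helpers import build_from_dataset
        cfg = SimConfig(seed=21, n_jobs=2, days_per_job=2, n_stations=5,
                        n_environments=3, n_events=2, mass_dt=120,
                        sigma2_day_range=(1e-6, 2e-6), trend_amplitude=0.05)
        ds = generate_dataset(cfg, include_number=False)
        design = build_from_dataset(ds, "PM2.5")
        spec = ModelSpec(chains=2, iterations=800, burn_in=300, seed=4)
        model = build_model(design, spec)
        draws = fit(model)
        pp = predict(model, draws, design)
        err = np.abs(pp["median_log10"].to_numpy() - design.y)
        assert np.mean(err < 0.05) >= 0.95
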