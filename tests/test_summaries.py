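"""Fold changes, elevation flags, GM/GSD tables, station correlations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pmspline.errors import PmsplineError
from pmspline.logbook import ShiftSeries
from pmspline.summaries import (EffectSummary, StationMetadata, flag_elevated,
                                fold_change_summary, gm_gsd, metadata_table,
                                station_correlations, design_type_means)


def _draws_with_alpha(alpha_matrix, stations):
    """Minimal PosteriorDraws stand-in for one station block."""
    from pmspline.model import PosteriorDraws
    c = 2
    n = alpha_matrix.shape[0] // c
    zeros = np.zeros((c, n, 1))
    return PosteriorDraws(
        alpha=alpha_matrix.reshape(c, n, -1), beta=zeros, gamma=zeros[:, :, :0],
        mu_day=zeros, sigma2_day=np.ones((c, n, 1)),
        m_job=zeros, tau2_job=np.ones((c, n, 1)),
        sigma2_zeta=np.ones((c, n)), zeta=None,
        stations=stations, environments=["E"], events=[],
        day_ids=["d01"], jobs=["station_agent"], seed=0, spec_hash="x")


class TestFoldChange:
    def test_zero_draws_give_unit_fold_change(self):
        draws = _draws_with_alpha(np.zeros((100, 2)), ["ref", "s2"])
        out = fold_change_summary(draws, "station")
        for s in out:
            assert (s.ci_low, s.fold_change_median, s.ci_high) == (1, 1, 1)

    def test_unit_coefficient_is_fold_change_ten(self):
        a = np.column_stack([np.zeros(100), np.ones(100)])
        out = fold_change_summary(_draws_with_alpha(a, ["ref", "s2"]),
                                  "station")
        assert out[1].fold_change_median == pytest.approx(10.0)

    def test_ten_percent_change(self, rng):
        a = np.column_stack([np.zeros(4000),
                             rng.normal(0.0414, 1e-6, 4000)])
        out = fold_change_summary(_draws_with_alpha(a, ["ref", "s2"]),
                                  "station")
        assert out[1].fold_change_median == pytest.approx(1.10, abs=1e-3)

    def test_reference_always_unit(self, small_fit):
        _, draws = small_fit
        for block in ("station", "environment"):
            s = fold_change_summary(draws, block)[0]
            assert (s.ci_low, s.fold_change_median, s.ci_high) == (1, 1, 1)
            assert not s.elevated

    def test_log10_shift_multiplies_summaries(self, small_fit):
        _, draws = small_fit
        base = fold_change_summary(draws, "station")
        shifted = dataclasses.replace(
            draws, alpha=draws.alpha + 0.3)
        out = fold_change_summary(shifted, "station")
        for b, s in zip(base, out):
            assert s.fold_change_median == pytest.approx(
                b.fold_change_median * 10 ** 0.3, rel=1e-9)
            assert s.ci_low == pytest.approx(b.ci_low * 10 ** 0.3, rel=1e-9)

    def test_interval_brackets_median(self, small_fit):
        _, draws = small_fit
        for s in fold_change_summary(draws, "environment"):
            assert s.ci_low <= s.fold_change_median <= s.ci_high > 0


class TestFlagElevated:
    def _summary(self, lo, med, hi, name="s"):
        return EffectSummary(name, "station", "PM2.5", med, lo, hi,
                             elevated=lo > 1,
                             borderline=0.98 < lo <= 1.0)

    def test_elevated_and_borderline_rules(self):
        pool = [self._summary(1.05, 1.1, 1.15, "up"),
                self._summary(0.99, 1.1, 1.2, "border"),
                self._summary(0.7, 0.9, 1.1, "flat")]
        elevated, borderline = flag_elevated(pool, delta=0.02)
        assert [s.category for s in elevated] == ["up"]
        assert [s.category for s in borderline] == ["border"]

    def test_subset_restriction(self):
        pool = [self._summary(1.1, 1.2, 1.3, "a"),
                self._summary(1.1, 1.2, 1.3, "b")]
        elevated, _ = flag_elevated(pool, subset=["b"])
        assert [s.category for s in elevated] == ["b"]

    def test_known_positive_effects_recovered(self):
        """Stations simulated with clearly elevated levels are the flagged
        ones when the design separates stations from days."""
        from pmspline.model import ModelSpec, build_model, fit
        from pmspline.simulate import SimConfig, generate_dataset
        from tests_helpers import build_from_dataset

        alpha = np.zeros(6)
        alpha[[2, 4]] = 0.30          # two stations at fold change ~2
        exact = 0
        n_rep = 4
        for rep in range(n_rep):
            cfg = SimConfig(seed=31 + rep, n_jobs=3, days_per_job=2,
                            n_stations=6, n_environments=3, n_events=2,
                            mass_dt=120, true_alpha=alpha,
                            true_beta=np.zeros(3), true_gamma=np.zeros(2),
                            tau2_job=(1e-3, 1e-3, 1e-3),
                            sigma2_day_range=(0.01, 0.02))
            ds = generate_dataset(cfg, include_number=False)
            design = build_from_dataset(ds, "PM2.5")
            draws = fit(build_model(design, ModelSpec(
                chains=2, iterations=1000, burn_in=400, seed=5)))
            out = fold_change_summary(draws, "station", fraction="PM2.5")
            flagged = {s.category for s in out if s.elevated}
            truly_up = {s for s, a in zip(cfg.stations, alpha) if a > 0}
            assert truly_up <= flagged      # never miss a real elevation
            exact += flagged == truly_up
        assert exact >= n_rep - 1           # rare borderline false flags only


class TestGmGsd:
    def _series(self, values, day_id="d01", job="station_agent",
                fraction="PM10"):
        rec = pd.DataFrame({
            "timestamp": pd.date_range("2019-10-07", periods=len(values),
                                       freq="5min"),
            "value": values})
        return ShiftSeries(day_id, job, fraction, rec)

    def test_geometric_mean_of_decades(self):
        out = gm_gsd([self._series([1.0, 10.0, 100.0])], "day")
        assert out["GM"].iloc[0] == pytest.approx(10.0, rel=1e-12)

    def test_constant_series(self):
        out = gm_gsd([self._series([7.0] * 5)], "day")
        assert out["GM"].iloc[0] == pytest.approx(7.0)
        assert out["GSD"].iloc[0] == pytest.approx(1.0)

    def test_lognormal_sample_matches_parameters(self, rng):
        vals = np.exp(rng.normal(1.0, 0.5, 100_000))
        out = gm_gsd([self._series(vals)], "day")
        assert out["GM"].iloc[0] == pytest.approx(np.e, rel=0.01)
        assert out["GSD"].iloc[0] == pytest.approx(np.exp(0.5), rel=0.01)

    def test_single_record_group_has_missing_gsd(self):
        out = gm_gsd([self._series([5.0])], "day")
        assert np.isnan(out["GSD"].iloc[0])

    def test_job_grouping_pools_days(self):
        s1 = self._series([1.0, 10.0], "d01", "security_guard")
        s2 = self._series([100.0], "d02", "security_guard")
        out = gm_gsd([s1, s2], "job")
        assert len(out) == 1 and out["n"].iloc[0] == 3
        assert out["GM"].iloc[0] == pytest.approx(10.0)

    @given(k=st.floats(0.01, 1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, k):
        vals = np.array([1.2, 3.4, 9.9, 2.2])
        base = gm_gsd([self._series(vals)], "day")
        scaled = gm_gsd([self._series(k * vals)], "day")
        assert scaled["GM"].iloc[0] == pytest.approx(k * base["GM"].iloc[0],
                                                     rel=1e-9)
        assert scaled["GSD"].iloc[0] == pytest.approx(base["GSD"].iloc[0],
                                                      rel=1e-9)


class TestStationCorrelations:
    def _summaries(self, coefs):
        return [EffectSummary(f"s{i}", "station", "PM2.5", 10.0 ** c,
                              10.0 ** (c - 0.01), 10.0 ** (c + 0.01),
                              elevated=False)
                for i, c in enumerate(coefs)]

    def _metadata(self, n, **cols):
        rows = [StationMetadata(station=f"s{i}",
                                **{k: v[i] for k, v in cols.items()})
                for i in range(n)]
        return metadata_table(rows)

    def test_exact_linear_relation(self):
        coefs = np.linspace(-0.1, 0.1, 10)
        meta = self._metadata(10, n_entrances=list(range(10)))
        out = station_correlations(self._summaries(coefs), meta)
        r = out.loc[out["covariate"] == "n_entrances", "r"].iloc[0]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_null_covariate_near_zero(self, rng):
        n = 1000
        coefs = rng.normal(0, 0.05, n)
        meta = self._metadata(n, n_entrances=list(
            rng.integers(1, 10, n)))
        out = station_correlations(self._summaries(coefs), meta)
        r = out.loc[out["covariate"] == "n_entrances", "r"].iloc[0]
        assert abs(r) < 0.08

    def test_symmetry_and_affine_invariance(self, rng):
        n = 30
        coefs = rng.normal(0, 0.05, n)
        x = rng.normal(50, 10, n)
        m1 = self._metadata(n, min_altitude=list(x))
        m2 = self._metadata(n, min_altitude=list(5.0 + 2.0 * x))
        s = self._summaries(coefs)

        def r_alt(meta):
            out = station_correlations(s, meta)
            return out.loc[out["covariate"] == "min_altitude", "r"].iloc[0]

        assert r_alt(m1) == pytest.approx(r_alt(m2), rel=1e-9)

    def test_zero_variance_covariate_missing(self):
        meta = self._metadata(5, n_ventilators=[3] * 5)
        out = station_correlations(self._summaries(np.linspace(0, .1, 5)),
                                   meta)
        assert np.isnan(out.loc[out["covariate"] == "n_ventilators",
                                "r"].iloc[0])

    def test_pairwise_missing_dropped(self):
        meta = self._metadata(6, n_entrances=[1, 2, 3, None, 5, 6])
        out = station_correlations(self._summaries(np.linspace(0, .1, 6)),
                                   meta)
        assert out.loc[out["covariate"] == "n_entrances", "n"].iloc[0] == 5

    def test_too_few_stations_raise(self):
        with pytest.raises(PmsplineError):
            station_correlations(self._summaries([0.1, 0.2]),
                                 self._metadata(2, n_entrances=[1, 2]))

    def test_design_type_means(self):
        meta = self._metadata(4)
        meta["design_type"] = ["A", "A", "B", "B"]
        out = design_type_means(self._summaries([0.0, 0.0, 0.1, 0.1]), meta)
        assert len(out) == 2
        assert out.loc[out["design_type"] == "B", "mean"].iloc[0] > \
            out.loc[out["design_type"] == "A", "mean"].iloc[0]

    def test_implausible_metadata_rejected(self):
        with pytest.raises(PmsplineError):
            StationMetadata("s", year_opened=1700)
        with pytest.raises(PmsplineError):
            StationMetadata("s", n_entrances=-1)
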