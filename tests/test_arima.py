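"""ARIMA-error ITS estimator: oracles, diagnostics, and recovery harness."""

import datetime as dt

import numpy as np
import pytest
from scipy import stats

import previts as pv
from previts.arima import ljung_box_q, stationary_r2, information_criteria, acf_pacf
from previts.interventions import PANDEMIC_EVENT


class TestDifference:
    def test_first_difference(self):
        np.testing.assert_array_equal(pv.difference([1, 3, 6], 1), [2, 3])

    def test_identity_at_d0(self):
        np.testing.assert_array_equal(pv.difference([4.0, 2.0], 0), [4.0, 2.0])

    def test_second_difference(self):
        np.testing.assert_array_equal(pv.difference([1, 3, 6, 10], 2), [1, 1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pv.difference([1.0], 1)


class TestLjungBox:
    def test_alternating_residuals_oracle(self):
        e = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        # rho_1 = -0.875 by direct evaluation; Q = n(n+2) rho^2/(n-1)
        q, p = ljung_box_q(e, max_lag=1)
        assert q == pytest.approx(8 * 10 * 0.875 ** 2 / 7)
        assert q == pytest.approx(8.75)
        assert p == pytest.approx(stats.chi2.sf(8.75, 1))

    def test_matches_statsmodels_on_random_inputs(self):
        from statsmodels.stats.diagnostic import acorr_ljungbox

        rng = np.random.default_rng(404)
        for _ in range(50):
            n = int(rng.integers(25, 80))
            m = int(rng.integers(1, 10))
            e = rng.normal(size=n)
            q, p = ljung_box_q(e, max_lag=m)
            ref = acorr_ljungbox(e, lags=[m])
            assert q == pytest.approx(ref["lb_stat"].iloc[0], abs=1e-8)
            assert p == pytest.approx(ref["lb_pvalue"].iloc[0], abs=1e-8)

    def test_model_df_shrinks_chi2_dof(self):
        e = np.sin(np.arange(40.0))
        q0, p0 = ljung_box_q(e, max_lag=6, model_df=0)
        q2, p2 = ljung_box_q(e, max_lag=6, model_df=2)
        assert q0 == q2
        assert p2 < p0  # same Q referred to fewer dof

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            _, p = ljung_box_q(rng.normal(size=100), max_lag=10)
            rejections += p < 0.05
        rate = rejections / reps
        assert rate == pytest.approx(0.05, abs=0.017)  # ~3 binomial SEs

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ljung_box_q(np.ones(30), max_lag=3)


class TestInformationCriteria:
    def test_zero_baseline(self):
        assert information_criteria(0.0, 0, 100) == 0.0

    def test_formula(self):
        assert information_criteria(-100.0, 3, 100) == pytest.approx(200 + 3 * np.log(100))

    def test_monotone_in_parameter_count(self):
        assert information_criteria(-50.0, 4, 80) > information_criteria(-50.0, 3, 80)


class TestStationaryR2:
    def test_perfect_fit(self):
        z = np.sin(np.arange(30.0)) * 3 + 10
        assert stationary_r2(np.zeros(29), z, d=1) == pytest.approx(1.0)

    def test_mean_only_model_is_zero(self):
        z = np.cumsum(np.random.default_rng(0).normal(size=40))
        dz = np.diff(z)
        assert stationary_r2(dz - dz.mean(), z, d=1) == pytest.approx(0.0, abs=1e-12)

    def test_fit_attached_value_matches_direct_sums(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        fit = pv.fit_its(series, design, (0, 1, 1))
        dz = np.diff(series.values)
        direct = 1 - np.sum(fit.residuals ** 2) / np.sum((dz - dz.mean()) ** 2)
        assert fit.stationary_r2 == pytest.approx(direct, abs=1e-8)


class TestAcfPacf:
    def test_lag0_and_definitional_identity(self):
        e = np.random.default_rng(3).normal(size=200)
        out = acf_pacf(e, max_lag=10)
        assert out["acf"][0] == pytest.approx(1.0)
        assert out["pacf"][1] == pytest.approx(out["acf"][1], abs=1e-6)
        assert out["band"] == pytest.approx(1.96 / np.sqrt(200))

    def test_ar1_autocorrelation_geometric_decay(self):
        sc = pv.Scenario(n_weeks=20000, d=0, ar_phi=0.6, ma_theta=0.0,
                         innovation_sd=1.0, drift=0, baseline=0.0, seed=8)
        u = pv.simulate_weekly_series(sc).values
        out = acf_pacf(u, max_lag=5)
        for k in (1, 2, 3):
            assert out["acf"][k] == pytest.approx(0.6 ** k, abs=0.03)


def _step_design(n_weeks, onset_week, lag=0):
    event = pv.InterruptionEvent(
        1,
        pv.DEFAULT_START + dt.timedelta(weeks=onset_week),
        "step",
        PANDEMIC_EVENT,
    )
    return pv.build_design_matrix([event], n_weeks=n_weeks, lag_weeks=lag)


class TestFitIts:
    def test_noise_free_step_recovered_exactly(self):
        design = _step_design(40, 14)
        z = pv.WeeklySeries(5.0 + 2.0 * design.matrix[:, 0], enforce_bounds=False)
        fit = pv.fit_its(z, design, (0, 0, 0), include_trend=True)
        assert fit.constant == pytest.approx(5.0, abs=1e-10)
        assert fit.effects[1]["estimate"] == pytest.approx(2.0, abs=1e-10)

    def test_ols_equivalence_on_random_inputs(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(30, 60))
            design = _step_design(n, int(rng.integers(5, n - 5)))
            z = pv.WeeklySeries(rng.normal(10, 2, n), enforce_bounds=False)
            fit = pv.fit_its(z, design, (0, 0, 0), include_trend=True)
            X = np.column_stack([np.ones(n), design.matrix])
            beta, *_ = np.linalg.lstsq(X, z.values, rcond=None)
            assert fit.constant == pytest.approx(beta[0], abs=1e-8)
            assert fit.effects[1]["estimate"] == pytest.approx(beta[1], abs=1e-8)

    def test_matches_statespace_ml_on_fixture(self, noisy_series_and_design):
        """Independent cross-check of the profile-GLS estimator against the
        state-space ML implementation in statsmodels."""
        import warnings

        import statsmodels.api as sm

        series, design, _ = noisy_series_and_design
        fit = pv.fit_its(series, design, (0, 1, 1), method="ml")
        exog = np.column_stack([np.arange(1.0, len(series) + 1), design.matrix])
        mod = sm.tsa.SARIMAX(series.values, exog=exog, order=(0, 1, 1), trend=None,
                             simple_differencing=True, concentrate_scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(disp=0, method="lbfgs", maxiter=500)
        assert fit.loglik >= res.llf - 1e-6   # exact optimum at least as good
        assert fit.ma_params[0] == pytest.approx(res.params[-1], abs=1e-3)
        np.testing.assert_allclose(
            fit.table["estimate"].to_numpy()[:12], res.params[:12], atol=2e-3
        )

    def test_scale_equivariance(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        fit1 = pv.fit_its(series, design, (0, 1, 1))
        scaled = pv.WeeklySeries(series.values * 3.0, start_date=series.start_date,
                                 enforce_bounds=False)
        fit3 = pv.fit_its(scaled, design, (0, 1, 1))
        assert fit3.constant == pytest.approx(3 * fit1.constant, rel=1e-6)
        for k in fit1.effects:
            assert fit3.effects[k]["estimate"] == pytest.approx(
                3 * fit1.effects[k]["estimate"], rel=1e-5, abs=1e-8
            )

    def test_ci_brackets_estimate_and_pvalues_valid(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        fit = pv.fit_its(series, design, (0, 1, 1))
        tab = fit.table[np.isfinite(fit.table["se"])]
        assert (tab["ci_lower"] <= tab["estimate"]).all()
        assert (tab["estimate"] <= tab["ci_upper"]).all()
        assert tab["p_value"].between(0, 1).all()
        assert len(fit.residuals) == fit.n_effective == len(series) - 1

    def test_collinear_design_rejected(self):
        a = pv.InterruptionEvent(1, dt.date(2019, 3, 1), "a", PANDEMIC_EVENT)
        b = pv.InterruptionEvent(2, dt.date(2019, 3, 2), "b", PANDEMIC_EVENT)
        dm = pv.build_design_matrix([a, b], n_weeks=30, lag_weeks=0)
        z = pv.WeeklySeries(np.random.default_rng(0).normal(10, 1, 30),
                            enforce_bounds=False)
        with pytest.raises(ValueError, match="collinear"):
            pv.fit_its(z, dm, (0, 0, 0))

    def test_missing_weeks_error_and_interpolation(self, default_design):
        vals = np.full(217, 10.0)
        vals[50] = np.nan
        z = pv.WeeklySeries(vals)
        with pytest.raises(ValueError, match="missing"):
            pv.fit_its(z, default_design, (0, 0, 0))
        fit = pv.fit_its(z, default_design, (0, 0, 0), interpolate_missing=True)
        assert "interpolated" in fit.messages[0]


class TestSelectOrder:
    def test_single_candidate_returned(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        order, table = pv.select_order(series, design, [(0, 1, 1)])
        assert order.as_tuple() == (0, 1, 1)
        assert len(table) == 1

    def test_selects_generating_order_in_majority(self):
        wins = 0
        reps = 40
        for r in range(reps):
            sc = pv.Scenario(drift=0.034, innovation_sd=0.5, ma_theta=0.5, d=1,
                             seed=5000 + r)
            z = pv.simulate_weekly_series(sc)
            order, _ = pv.select_order(
                z, sc.design(), [(0, 0, 0), (0, 1, 1), (1, 0, 0)]
            )
            wins += order.as_tuple() == (0, 1, 1)
        assert wins / reps > 0.5

    def test_bic_tie_breaks_on_complexity(self, monkeypatch):
        import pandas as pd

        import previts.arima as arima_mod

        series = pv.WeeklySeries(np.random.default_rng(1).normal(10, 1, 60),
                                 enforce_bounds=False)
        design = _step_design(60, 20)

        real_fit = arima_mod.fit_its

        def fake_fit(series_, design_, order, **kw):
            fit = real_fit(series_, design_, (0, 0, 0), **kw)
            object.__setattr__(fit, "bic", 100.0)
            object.__setattr__(fit, "ljung_box_pvalue", 0.5)
            return fit

        monkeypatch.setattr(arima_mod, "fit_its", fake_fit)
        order, _ = arima_mod.select_order(series, design, [(1, 0, 1), (0, 0, 1)])
        assert order.as_tuple() == (0, 0, 1)


class TestRecoveryStudy:
    def test_summary_structure_and_null_behavior(self):
        sc = pv.Scenario(baseline=12.0, innovation_sd=1.0, ma_theta=0.0, d=0,
                         effects={}, seed=606)
        res = pv.recovery_study(sc, reps=60, order=(0, 0, 0), seed=606)
        summary = res["summary"]
        assert set(summary["event"]) == {e.id for e in pv.default_calendar()}
        assert res["failure_share"] == 0.0
        # null effects: bias within 3 MC SEs, moderate rejection
        for _, row in summary.iterrows():
            assert abs(row["bias"]) < 3 * row["mc_se"] + 1e-12
        assert summary["rejection_rate"].mean() < 0.2
        assert res["constant"]["truth"] == 12.0
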