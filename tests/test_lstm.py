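"""Mean-variance LSTM: loss exactness, gradients, windowing, training."""

import numpy as np
import pytest

import previts as pv
from previts.lstm import MeanVarianceLSTM


class TestSoftplus:
    def test_closed_form_values(self):
        assert pv.softplus(0.0) == pytest.approx(np.log(2))
        assert pv.softplus(50.0) == pytest.approx(50.0, abs=1e-12)
        assert pv.softplus(-20.0) == pytest.approx(2.0611536e-9, rel=1e-5)

    def test_positive_increasing_and_close_to_relu(self):
        x = np.linspace(-30, 30, 301)
        y = pv.softplus(x)
        assert (y > 0).all()
        assert (np.diff(y) > 0).all()
        assert np.max(np.abs(y - np.maximum(x, 0))) <= np.log(2) + 1e-12


class TestGaussianNll:
    def test_exact_values(self):
        assert pv.gaussian_nll(0.0, 0.0, 1.0) == pytest.approx(0.5 * np.log(2 * np.pi))
        assert pv.gaussian_nll(3.0, 3.0, np.sqrt(1 / (2 * np.pi))) == pytest.approx(0.0, abs=1e-12)

    def test_batch_mean(self):
        y = np.array([0.0, 1.0])
        val = pv.gaussian_nll(y, np.zeros(2), np.ones(2))
        single = [pv.gaussian_nll(v, 0.0, 1.0) for v in y]
        assert val == pytest.approx(np.mean(single))

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            pv.gaussian_nll(0.0, 0.0, 0.0)

    def test_minimized_at_sigma2_equal_squared_error(self):
        y, mu = 2.0, 0.5
        s_star = abs(y - mu)
        eps = 1e-5
        f = lambda s: pv.gaussian_nll(y, mu, s)
        grad = (f(s_star + eps) - f(s_star - eps)) / (2 * eps)
        assert grad == pytest.approx(0.0, abs=1e-6)
        assert f(s_star) < f(s_star * 1.3)
        assert f(s_star) < f(s_star * 0.7)

    def test_finite_difference_gradients(self):
        y, mu, sigma = 1.3, 0.4, 0.8
        eps = 1e-6
        d_mu = (pv.gaussian_nll(y, mu + eps, sigma) - pv.gaussian_nll(y, mu - eps, sigma)) / (2 * eps)
        d_sig = (pv.gaussian_nll(y, mu, sigma + eps) - pv.gaussian_nll(y, mu, sigma - eps)) / (2 * eps)
        assert d_mu == pytest.approx(-(y - mu) / sigma ** 2, abs=1e-5)
        assert d_sig == pytest.approx(1 / sigma - (y - mu) ** 2 / sigma ** 3, abs=1e-5)


class TestMakeWindows:
    def test_boundary_sample_count(self):
        s = pv.WeeklySeries(np.linspace(5, 10, 13))
        ds = pv.make_windows(s, None, pv.LstmConfig(window=12, train_fraction=0.5))
        assert ds.n_samples == 1

    def test_default_count_on_study_grid(self, default_design):
        s = pv.WeeklySeries(np.full(217, 10.0))
        ds = pv.make_windows(s, default_design, pv.LstmConfig())
        assert ds.n_samples == 205
        assert ds.split == int(0.8 * 205)

    def test_indicator_features_match_design_exactly(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        ds = pv.make_windows(series, design, pv.LstmConfig())
        i = 37
        np.testing.assert_array_equal(ds.inputs[i][:, 1:], design.matrix[i:i + 12])
        # target is the standardized next-week value, never inside its window
        assert ds.target_weeks[i] == i + 12
        assert ds.targets[i] == pytest.approx(
            (series.values[i + 12] - ds.mean) / ds.sd
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            pv.make_windows(pv.WeeklySeries(np.ones(10)), None, pv.LstmConfig(window=12))


class TestNetworkGradients:
    def test_bptt_matches_finite_differences(self):
        cfg = pv.LstmConfig(window=5, hidden_units=4, seed=3)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 5, 2))
        y = rng.normal(size=3)
        model = MeanVarianceLSTM(2, cfg)
        _, grads = model.loss_and_grads(x, y)
        eps = 1e-6
        for name in ("Wx0", "Wh0", "b0", "Wm", "Wv", "bm", "bv"):
            v = model.params[name]
            flat = v.reshape(-1)
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                lp, _ = model.loss_and_grads(x, y)
                flat[i] = old - eps
                lm, _ = model.loss_and_grads(x, y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert grads[name].reshape(-1)[i] == pytest.approx(num, abs=1e-5)


class TestTraining:
    def test_constant_series_learned_with_shrinking_scale(self):
        cfg = pv.LstmConfig(seed=0)
        s = pv.WeeklySeries(np.full(60, 15.0))
        ds = pv.make_windows(s, None, cfg)
        model, hist = pv.train(ds, cfg)
        assert hist.train_mse[-1] < 1e-3
        fc = pv.predict_distribution(model, ds)
        assert (fc.sigma > 0).all()

    def test_seeded_determinism(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        cfg = pv.LstmConfig(seed=5, epochs=2)
        ds = pv.make_windows(series, design, cfg)
        _, h1 = pv.train(ds, cfg)
        _, h2 = pv.train(ds, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.test_mse == h2.test_mse

    def test_interval_definition_and_positivity(self, noisy_series_and_design):
        series, design, _ = noisy_series_and_design
        cfg = pv.LstmConfig(seed=1, epochs=2)
        ds = pv.make_windows(series, design, cfg)
        model, _ = pv.train(ds, cfg)
        fc = pv.predict_distribution(model, ds)
        assert (fc.sigma > 0).all()
        np.testing.assert_allclose(fc.upper - fc.lower, 2 * 1.96 * fc.sigma, rtol=1e-12)
        assert (fc.lower < fc.upper).all()
        assert fc.target_weeks[0] == cfg.window

    def test_step_effect_sign_recovered_against_counterfactual(self):
        """With the intervention feature zeroed, post-onset predictions move
        in the direction opposite the injected (negative) step."""
        hits = 0
        seeds = range(5)
        for seed in seeds:
            sc = pv.Scenario(innovation_sd=0.3, d=0, ma_theta=0.0, drift=0.0,
                             baseline=12.0, effects={2: -4.0}, seed=100 + seed)
            z = pv.simulate_weekly_series(sc)
            dm = sc.design()
            cfg = pv.LstmConfig(seed=seed)
            ds = pv.make_windows(z, dm, cfg)
            model, _ = pv.train(ds, cfg)
            fc = pv.predict_distribution(model, ds)
            zero_design = pv.DesignMatrix(
                matrix=np.zeros_like(dm.matrix), events=dm.events,
                lag_weeks=dm.lag_weeks, start_date=dm.start_date,
            )
            ds0 = pv.make_windows(z, zero_design, cfg)
            # reuse the train-split statistics so predictions are comparable
            fc0 = pv.predict_distribution(model, ds0)
            onset = pv.lagged_onset(
                next(e for e in dm.events if e.id == 2), sc.start_date, sc.lag_weeks
            )
            post = fc.target_weeks >= onset
            hits += (fc.mu[post].mean() - fc0.mu[post].mean()) < 0
        assert hits >= 4


class TestRmse:
    def test_examples(self):
        assert pv.rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert pv.rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_consistency_with_mse(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert pv.rmse(a, b) ** 2 == pytest.approx(np.mean((a - b) ** 2))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pv.rmse([1.0], [1.0, 2.0])
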