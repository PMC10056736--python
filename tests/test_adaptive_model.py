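import numpy as np
import pytest
from sklearn.base import clone

from glytwin.adaptive_model import (RecursiveGlucoseModel,
                                    initial_state, predict_one_step,
                                    rls_update, fit_series)

from conftest import make_series


def batch_solution(X, y, lam, w0, p0_scale, obs_weight=1.0):
    """Closed-form minimizer of the discounted criterion with its prior.

    Independent normal-equations oracle: lam-discounted weighted residuals
    plus the prior penalty lam**N (w-w0)' P0^{-1} (w-w0) implied by the
    recursive estimator's starting p_matrix.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    p0_inv = np.eye(X.shape[1]) / p0_scale
    wts = obs_weight * lam ** (n - 1 - np.arange(n))
    a = lam ** n * p0_inv + (X.T * wts) @ X
    b = lam ** n * p0_inv @ np.asarray(w0, float) + (X.T * wts) @ y
    return np.linalg.solve(a, b)


def exciting_data(n, w_true=(0.9, -0.5, 0.2), seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    w_true = np.asarray(w_true)
    g = 120.0
    X, y = [], []
    for _ in range(n):
        h = np.array([g, rng.uniform(0, 3), rng.uniform(0, 40)])
        target = float(h @ w_true) + rng.normal(0, noise)
        X.append(h)
        y.append(target)
        g = max(target, 40.0)
    return np.array(X), np.array(y)


class TestPrediction:
    @pytest.mark.parametrize("w, h, expected", [
        ((1, 0, 0), (120, 5, 30), 120.0),
        ((0.9, -1.0, 0.1), (120, 2, 30), 109.0),
        ((0, 0, 0), (120, 2, 30), 0.0),
    ])
    def test_linear_form(self, w, h, expected):
        state = initial_state(init_w=w)
        assert predict_one_step(state, h) == pytest.approx(expected)


class TestUpdate:
    def test_zero_innovation_leaves_w_unchanged(self):
        state = initial_state(init_w=(0.9, -1.0, 0.1))
        h = np.array([100.0, 1.0, 10.0])
        new = rls_update(state, h, float(h @ state.w))
        assert np.allclose(new.w, state.w)

    def test_dead_zone_skips_update_entirely(self):
        state = initial_state(dead_zone=5.0)
        h = np.array([100.0, 1.0, 10.0])
        new = rls_update(state, h, float(h @ state.w) + 4.9)
        assert new is state

    def test_recursion_equals_batch_on_every_prefix(self):
        """lam=1 recursive estimate is the regularized LS solution."""
        X, y = exciting_data(60, noise=2.0, seed=3)
        state = initial_state(lam=1.0)
        for k in range(60):
            state = rls_update(state, X[k], y[k])
            expected = batch_solution(X[:k + 1], y[:k + 1], lam=1.0,
                                      w0=(0.9, -0.5, 0.1), p0_scale=1e3)
            assert np.allclose(state.w, expected, atol=1e-8)

    def test_forgetting_recursion_equals_discounted_batch(self):
        X, y = exciting_data(80, noise=1.0, seed=5)
        state = initial_state(lam=0.95)
        for k in range(80):
            state = rls_update(state, X[k], y[k])
        expected = batch_solution(X, y, lam=0.95, w0=(0.9, -0.5, 0.1),
                                  p0_scale=1e3)
        assert np.allclose(state.w, expected, atol=1e-7)

    def test_noiseless_parameter_recovery(self):
        w_true = (0.9, -0.5, 0.2)
        X, y = exciting_data(200, w_true=w_true, seed=0)
        state = initial_state(lam=1.0)
        for k in range(200):
            state = rls_update(state, X[k], y[k])
        assert np.linalg.norm(state.w - w_true) < 1e-6

    def test_sign_projection_enforced(self):
        state = initial_state(init_w=(0.9, -0.1, 0.01),
                              sign_projection=True)
        # data pushing z2 positive and z3 negative
        rng = np.random.default_rng(2)
        for _ in range(50):
            h = np.array([100.0, rng.uniform(0, 3), rng.uniform(0, 40)])
            state = rls_update(state, h, 0.95 * 100 + 2.0 * h[1])
        assert state.w[1] <= 0.0
        assert state.w[2] >= 0.0
        assert 0.0 <= state.w[0] <= 1.2

    def test_p_matrix_stays_positive_definite_long_run(self):
        rng = np.random.default_rng(1)
        state = initial_state(lam=0.98)
        for _ in range(10_000):
            h = np.array([rng.uniform(60, 250), rng.uniform(0, 3),
                          rng.uniform(0, 50)])
            state = rls_update(state, h, float(h @ state.w)
                               + rng.normal(0, 3))
        assert np.linalg.eigvalsh(state.p_matrix).min() > 0

    def test_trace_cap_bounds_covariance(self):
        state = initial_state(lam=0.9, p_trace_max=3e3)
        h = np.array([100.0, 1.0, 0.0])  # persistently unexciting
        for _ in range(500):
            state = rls_update(state, h, float(h @ state.w) + 10.0)
        assert np.trace(state.p_matrix) <= 3e3 * (1 + 1e-9)

    def test_corrupt_state_signalled(self):
        state = initial_state()
        with pytest.raises(ValueError, match="finite"):
            rls_update(state, np.array([np.nan, 0, 0]), 100.0)


class TestFitSeries:
    def test_noiseless_series_residuals_vanish(self):
        w_true = np.array([0.9, -0.8, 0.15])
        rng = np.random.default_rng(7)
        n = 400
        # input ranges keep the drug-free recursion well above zero, so
        # every transition is exactly linear in the regressors
        ins = rng.uniform(0, 1, n)
        cho = rng.uniform(30, 80, n)
        g = np.empty(n)
        g[0] = 120.0
        for k in range(n - 1):
            g[k + 1] = w_true @ np.array([g[k], ins[k], cho[k]])
        assert g.min() > 40
        report = fit_series(make_series(g, ins, cho), lam=0.98)
        assert np.sqrt(np.mean(report.residuals[n // 2:] ** 2)) < 1e-6

    def test_constant_series_residuals_converge(self):
        report = fit_series(make_series(np.full(120, 140.0)), lam=0.99)
        assert np.abs(report.residuals[-20:]).max() < 1e-6

    def test_forgetting_value_does_not_move_noiseless_fixed_point(self):
        w_true = np.array([0.88, -0.6, 0.2])
        rng = np.random.default_rng(9)
        n = 300
        ins = rng.uniform(0, 1, n)
        cho = rng.uniform(30, 80, n)
        g = np.empty(n)
        g[0] = 110.0
        for k in range(n - 1):
            g[k + 1] = w_true @ np.array([g[k], ins[k], cho[k]])
        assert g.min() > 40
        series = make_series(g, ins, cho)
        for lam in (0.92, 0.96, 1.0):
            report = fit_series(series, lam=lam)
            assert np.allclose(report.final_state.w, w_true, atol=1e-5)

    def test_gappy_series_rejected(self):
        s = make_series([100, np.nan, 120, 110, 115],
                        mask=[1, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="impute"):
            fit_series(s)


def test_forgetting_tracks_step_change_better():
    """After an abrupt parameter change, smaller lam reaches a smaller
    steady residual than lam=1 on identical data."""
    rng = np.random.default_rng(4)
    n = 400
    g = 120.0
    X, y = [], []
    for k in range(n):
        w_true = np.array([0.9, -0.5, 0.2]) if k < n // 2 else \
            np.array([0.95, -1.5, 0.1])
        h = np.array([g, rng.uniform(0, 3), rng.uniform(0, 40)])
        target = float(h @ w_true)
        X.append(h)
        y.append(target)
        g = max(target, 40.0)

    def tail_rms(lam):
        state = initial_state(lam=lam)
        resid = []
        for h, target in zip(X, y):
            resid.append(target - predict_one_step(state, h))
            state = rls_update(state, h, target)
        return float(np.sqrt(np.mean(np.array(resid[-50:]) ** 2)))

    assert tail_rms(0.95) < tail_rms(1.0)


class TestSklearnWrapper:
    def test_fit_predict_and_clone(self):
        X, y = exciting_data(100, seed=6)
        model = RecursiveGlucoseModel(lam=1.0).fit(X, y)
        assert np.allclose(model.predict(X[:5]), X[:5] @ model.w_)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
        assert not hasattr(cloned, "w_")

    def test_partial_fit_continues_state(self):
        X, y = exciting_data(100, seed=6)
        a = RecursiveGlucoseModel(lam=1.0).fit(X, y)
        b = RecursiveGlucoseModel(lam=1.0).fit(X[:50], y[:50])
        b.partial_fit(X[50:], y[50:])
        assert np.allclose(a.w_, b.w_)
        assert b.n_updates_ == 100


class TestPersistence:
    def test_state_round_trips_through_text_file(self, tmp_path):
        X, y = exciting_data(40, seed=8, noise=1.0)
        state = initial_state(lam=0.95, dead_zone=2.0, sign_projection=True,
                              p_trace_max=5e3)
        for h, target in zip(X, y):
            state = rls_update(state, h, target)
        from glytwin.adaptive_model import save_state, load_state
        path = tmp_path / "state.txt"
        save_state(state, path)
        loaded = load_state(path)
        assert np.array_equal(loaded.w, state.w)
        assert np.array_equal(loaded.p_matrix, state.p_matrix)
        assert loaded.lam == state.lam
        assert loaded.dead_zone == state.dead_zone
        assert loaded.sign_projection == state.sign_projection

    def test_fit_report_csv(self, tmp_path):
        import pandas as pd
        X, y = exciting_data(30, seed=8)
        g = np.concatenate([[120.0], y])
        report = fit_series(make_series(g, np.append(X[:, 1], 0),
                                        np.append(X[:, 2], 0)), lam=1.0)
        path = tmp_path / "fit.csv"
        report.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["epoch", "z1", "z2", "z3", "residual"]
        assert len(df) == len(report.residuals)
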