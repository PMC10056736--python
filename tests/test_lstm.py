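import json

import numpy as np
import pytest

from glytwin.lstm import (ForecastConfig, LSTMForecaster, make_supervised,
                          lstm_cell, save_json, load_json, _init_layer)
from glytwin.patient_sim import TherapySchedule, simulate_open_loop
from conftest import make_series

TINY = ForecastConfig(window=8, horizon_nc=4, hidden_layers=2,
                      hidden_units=8, epochs=30, patience=10,
                      learning_rate=0.02, batch_size=32, seed=0)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def hand_cell(layer, z, c_prev):
    """Scalar re-implementation of the gate equations, used as oracle."""
    n_h = len(layer["bi"])
    h = np.zeros(n_h)
    c = np.zeros(n_h)
    for j in range(n_h):
        i_j = sigmoid(np.dot(layer["wi"][j], z) + layer["bi"][j])
        f_j = sigmoid(np.dot(layer["wf"][j], z) + layer["bf"][j])
        o_j = sigmoid(np.dot(layer["wo"][j], z) + layer["bo"][j])
        g_j = np.tanh(np.dot(layer["wc"][j], z) + layer["bc"][j])
        c[j] = f_j * c_prev[j] + i_j * g_j
        h[j] = o_j * np.tanh(c[j])
    return h, c


def plant_series(days=4, noise=0.0, seed=11):
    from glytwin.patient_sim import PatientProfile, VirtualPatientParams
    profile = PatientProfile(id="L", age=66, sex="M", bmi=27,
                             target_band=(80, 180), avg_cho_per_day=240,
                             lifestyle="moderate")
    params = VirtualPatientParams(true_w=(0.9, -1.5, 0.12),
                                  basal_glucose=140.0,
                                  process_noise_sd=noise,
                                  measurement_noise_sd=noise)
    therapy = TherapySchedule(basal_per_epoch=0.6, carb_ratio=0.08)
    return simulate_open_loop(params, profile, therapy, days, seed)


@pytest.fixture(scope="module")
def trained():
    series = plant_series()
    model = LSTMForecaster.from_config(TINY).fit(series)
    return model, series


class TestSupervised:
    def test_pair_count_is_length_minus_window(self):
        s = make_series(100 + np.sin(np.arange(100)) * 10)
        x, y, _ = make_supervised(s, TINY)
        assert len(x) == 100 - TINY.window
        assert x.shape == (92, 8, 3)

    def test_training_targets_scaled_to_unit_interval(self):
        s = plant_series(days=2)
        cfg = TINY
        x, y, _ = make_supervised(s, cfg)
        n_train = int(len(s) * cfg.train_fraction) - cfg.window
        assert (y[:n_train] >= 0).all() and (y[:n_train] <= 1).all()

    def test_windows_invert_to_raw_samples(self):
        s = plant_series(days=2)
        x, _, scaler = make_supervised(s, TINY)
        raw = x[0] * scaler.span + scaler.offset
        assert np.allclose(raw[:, 0], s.bgl[:8])

    def test_constant_channel_flagged(self):
        s = make_series(np.full(60, 120.0))
        with pytest.warns(UserWarning, match="constant channel"):
            make_supervised(s, TINY)


class TestGateAlgebra:
    def test_production_cell_matches_hand_rolled(self):
        rng = np.random.default_rng(0)
        layer = _init_layer(rng, n_in=3, n_hidden=5)
        for key in layer:
            layer[key] = rng.normal(scale=0.5, size=layer[key].shape)
        z = rng.normal(size=(1, 8))
        c_prev = rng.normal(size=(1, 5))
        h, c, _ = lstm_cell(layer, z, c_prev)
        h_ref, c_ref = hand_cell(layer, z[0], c_prev[0])
        assert np.allclose(h[0], h_ref, atol=1e-6)
        assert np.allclose(c[0], c_ref, atol=1e-6)


class TestTraining:
    def test_noiseless_plant_error_below_reported_range(self, trained):
        model, _ = trained
        assert model.report_.pct_error < 5.16

    def test_training_is_deterministic(self):
        series = plant_series(days=2)
        cfg = ForecastConfig(window=8, horizon_nc=4, hidden_units=4,
                             epochs=5, seed=3)
        a = LSTMForecaster.from_config(cfg).fit(series)
        b = LSTMForecaster.from_config(cfg).fit(series)
        assert a.report_.rmse_norm == b.report_.rmse_norm

    def test_constant_series_predicts_the_constant(self):
        s = make_series(np.full(120, 140.0))
        with pytest.warns(UserWarning, match="constant channel"):
            model = LSTMForecaster(window=8, hidden_units=4, epochs=20,
                                   seed=1).fit(s)
        hist = np.column_stack([np.full(8, 140.0), np.zeros(8),
                                np.zeros(8)])
        fc = model.forecast_recursive(hist, 4, np.zeros((4, 2)))
        assert np.allclose(fc, 140.0, atol=1.0)

    def test_excluded_interval_drops_training_pairs(self):
        series = plant_series(days=2)
        cfg = ForecastConfig(window=8, hidden_units=4, epochs=2,
                             excluded_interval=(300.0, 900.0), seed=0)
        model = LSTMForecaster.from_config(cfg).fit(series)
        assert model.report_.pct_error >= 0  # trains without error


class TestRecursiveForecast:
    def test_one_step_rollout_equals_single_prediction(self, trained):
        model, series = trained
        hist = np.column_stack([series.bgl[50:58], series.insulin[50:58],
                                series.cho[50:58]])
        fut = np.column_stack([series.insulin[58:59], series.cho[58:59]])
        roll = model.forecast_recursive(hist, 1, fut)
        one = model.predict(hist[None])
        assert roll[0] == pytest.approx(one[0])

    def test_rollout_error_growth_bounded(self, trained):
        """Mean 4-step error stays within 2x the 1-step error."""
        model, series = trained
        one_step, multi = [], []
        for k in range(100, 300, 7):
            hist = np.column_stack([series.bgl[k:k + 8],
                                    series.insulin[k:k + 8],
                                    series.cho[k:k + 8]])
            fut = np.column_stack([series.insulin[k + 8:k + 12],
                                   series.cho[k + 8:k + 12]])
            fc = model.forecast_recursive(hist, 4, fut)
            actual = series.bgl[k + 8:k + 12]
            one_step.append(abs(fc[0] - actual[0]))
            multi.append(np.mean(np.abs(fc - actual)))
        assert np.mean(multi) < 2 * np.mean(one_step) + 0.5

    def test_bad_inputs_rejected(self, trained):
        model, series = trained
        hist = np.column_stack([series.bgl[:8], series.insulin[:8],
                                series.cho[:8]])
        with pytest.raises(ValueError, match="steps"):
            model.forecast_recursive(hist, 0, np.zeros((0, 2)))
        with pytest.raises(ValueError, match="shape"):
            model.forecast_recursive(hist[:5], 2, np.zeros((2, 2)))


class TestEvaluate:
    def test_hand_computed_percentage_error(self, trained):
        model, _ = trained

        class Stub(LSTMForecaster):
            def predict_scaled(self, x):
                return self._stub_values

        stub = Stub(window=2)
        stub.scaler_ = model.scaler_
        # raw targets 100, 200; raw predictions 110, 180
        y_scaled = stub.scaler_.scale_glucose(np.array([100.0, 200.0]))
        stub._stub_values = stub.scaler_.scale_glucose(
            np.array([110.0, 180.0]))
        report = stub._evaluate_pairs(np.zeros((2, 2, 3)), y_scaled)
        assert report.pct_error == pytest.approx(10.0)
        assert report.rmse_norm >= 0 and report.mae_norm >= 0

    def test_perfect_prediction_scores_zero(self, trained):
        model, _ = trained

        class Stub(LSTMForecaster):
            def predict_scaled(self, x):
                return self._stub_values

        stub = Stub(window=2)
        stub.scaler_ = model.scaler_
        y = stub.scaler_.scale_glucose(np.array([120.0, 130.0]))
        stub._stub_values = y.copy()
        report = stub._evaluate_pairs(np.zeros((2, 2, 3)), y)
        assert (report.pct_error, report.rmse_norm, report.mae_norm) \
            == (0.0, 0.0, 0.0)


class TestPersistence:
    def test_save_load_round_trip_bit_exact(self, trained, tmp_path):
        model, series = trained
        path = tmp_path / "model.json"
        save_json(model, path)
        loaded = load_json(path)
        hist = np.column_stack([series.bgl[20:28], series.insulin[20:28],
                                series.cho[20:28]])
        fut = np.column_stack([series.insulin[28:32], series.cho[28:32]])
        assert np.array_equal(model.forecast_recursive(hist, 4, fut),
                              loaded.forecast_recursive(hist, 4, fut))

    def test_json_has_two_layers_of_gate_arrays(self, trained, tmp_path):
        model, _ = trained
        path = tmp_path / "model.json"
        save_json(model, path)
        payload = json.loads(path.read_text())
        assert len(payload["layers"]) == 2
        for layer in payload["layers"]:
            assert set(layer) == {"wi", "wf", "wo", "wc",
                                  "bi", "bf", "bo", "bc"}

    def test_truncated_file_raises_schema_error(self, trained, tmp_path):
        model, _ = trained
        path = tmp_path / "model.json"
        save_json(model, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ValueError, match="truncated|JSON"):
            load_json(path)

    def test_unknown_schema_version_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(json.dumps({"schema_version": 99}))
        with pytest.raises(ValueError, match="schema"):
            load_json(path)
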