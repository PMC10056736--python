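"""Multivariate multi-step blood-glucose forecasting with a stacked LSTM.

The forecaster consumes sliding windows (default 2 h = 8 samples) of the
three channels (glucose mg/dL, insulin U/epoch, carbohydrate g/epoch),
min/max-scaled to [0, 1] using training-split statistics only, and predicts
the next glucose sample.  Multi-step forecasts are produced recursively
("time segmentation"): each predicted glucose value is fed back as the
glucose input of the next window while insulin and carbohydrates over the
horizon come from announced schedules.

The network is a standard two-hidden-layer LSTM with a linear readout,
implemented directly in numpy (forward pass, backpropagation through time,
Adam), which keeps training deterministic under a fixed seed and the model
trivially serializable to JSON.  Gate equations, per layer and time step
with ``z = [h_{t-1}, x_t]``:

    i = sigmoid(Wi z + bi)      f = sigmoid(Wf z + bf)
    o = sigmoid(Wo z + bo)      g = tanh(Wc z + bc)
    c_t = f * c_{t-1} + i * g   h_t = o * tanh(c_t)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .series import GlucoseSeries

SCHEMA_VERSION = 1
_GATES = ("wi", "wf", "wo", "wc", "bi", "bf", "bo", "bc")


@dataclass(frozen=True)
class ForecastConfig:
    """Hyperparameters of the forecaster.

    ``window`` and ``horizon_nc`` are in samples (8 = 2 h, 4 = 1 h at the
    15-min grid).  ``excluded_interval`` optionally removes a time span
    (minutes pair) from the training pairs, e.g. a known sensor outage.
    """

    window: int = 8
    horizon_nc: int = 4
    hidden_layers: int = 2
    hidden_units: int = 32
    epochs: int = 200
    train_fraction: float = 0.70
    excluded_interval: tuple[float, float] | None = None
    seed: int = 0
    learning_rate: float = 0.01
    batch_size: int = 64
    patience: int = 20
    #: optional fixed per-channel (min, max) pairs for the [0, 1] scaling,
    #: e.g. physiological bounds.  ``None`` means min/max of the training
    #: split.  Fixed bounds matter when the model must extrapolate to
    #: glucose levels outside its training range (closed-loop use).
    scaling: tuple | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.horizon_nc < 1:
            raise ValueError("window and horizon must be at least 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.hidden_layers < 1 or self.hidden_units < 1:
            raise ValueError("need at least one hidden layer and unit")


@dataclass(frozen=True)
class ForecastReport:
    """Held-out error summary.

    ``pct_error`` is the mean absolute percentage error on the raw mg/dL
    scale; ``rmse_norm`` and ``mae_norm`` are computed on the [0, 1]-scaled
    glucose channel.  ``n_excluded`` counts zero-valued targets skipped by
    the percentage error.
    """

    pct_error: float
    rmse_norm: float
    mae_norm: float
    n_excluded: int = 0


class _Scaler:
    """Per-channel min/max scaling to [0, 1]; identity on flat channels."""

    def __init__(self, mins, maxs):
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        span = self.maxs - self.mins
        flat = span <= 0
        if flat.any():
            warnings.warn("constant channel(s) found; scale factor set to "
                          "identity for them (offset shift only)",
                          stacklevel=3)
        self.span = np.where(flat, 1.0, span)
        self.offset = self.mins

    @classmethod
    def from_data(cls, x: np.ndarray) -> "_Scaler":
        return cls(x.min(axis=0), x.max(axis=0))

    def transform(self, x):
        return (np.asarray(x, dtype=float) - self.offset) / self.span

    def inverse_glucose(self, y):
        return np.asarray(y, dtype=float) * self.span[0] + self.offset[0]

    def scale_glucose(self, y):
        return (np.asarray(y, dtype=float) - self.offset[0]) / self.span[0]


def _channels(series: GlucoseSeries) -> np.ndarray:
    return np.column_stack([series.bgl, series.insulin, series.cho])


def make_supervised(series: GlucoseSeries, config: ForecastConfig,
                    scaler: _Scaler | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, _Scaler]:
    """Sliding windows of scaled channels and next-glucose targets.

    A series of length L yields ``L - window`` one-step pairs.  When no
    scaler is passed, scaling statistics come from the chronological
    training split only, never from held-out data.
    """
    if len(series) <= config.window + config.horizon_nc:
        raise ValueError("series too short for the window and horizon")
    raw = _channels(series)
    if scaler is None:
        if config.scaling is not None:
            pairs = np.asarray(config.scaling, dtype=float)
            scaler = _Scaler(pairs[:, 0], pairs[:, 1])
        else:
            n_train = int(len(series) * config.train_fraction)
            scaler = _Scaler.from_data(raw[:max(n_train, 2)])
    scaled = scaler.transform(raw)
    w = config.window
    n_pairs = len(series) - w
    idx = np.arange(n_pairs)[:, None] + np.arange(w)[None, :]
    x = scaled[idx]                      # (n_pairs, window, 3)
    y = scaled[np.arange(w, len(series)), 0]
    return x, y, scaler


# ---------------------------------------------------------------------------
# numpy LSTM core


def _init_layer(rng: np.random.Generator, n_in: int, n_hidden: int) -> dict:
    s = 1.0 / np.sqrt(n_in + n_hidden)
    layer = {}
    for gate in ("wi", "wf", "wo", "wc"):
        layer[gate] = rng.uniform(-s, s, size=(n_hidden, n_hidden + n_in))
    for gate in ("bi", "bo", "bc"):
        layer[gate] = np.zeros(n_hidden)
    layer["bf"] = np.ones(n_hidden)  # forget-bias init eases gradient flow
    return layer


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_cell(layer: dict, z: np.ndarray, c_prev: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Single gate evaluation; ``z`` is the concatenated [h_prev, x]."""
    i = _sigmoid(z @ layer["wi"].T + layer["bi"])
    f = _sigmoid(z @ layer["wf"].T + layer["bf"])
    o = _sigmoid(z @ layer["wo"].T + layer["bo"])
    g = np.tanh(z @ layer["wc"].T + layer["bc"])
    c = f * c_prev + i * g
    tc = np.tanh(c)
    h = o * tc
    cache = {"z": z, "i": i, "f": f, "o": o, "g": g,
             "c_prev": c_prev, "tc": tc}
    return h, c, cache


def _forward(layers, readout, x):
    """Full forward pass; returns predictions and the BPTT caches."""
    n, t_len, _ = x.shape
    inputs = x
    caches = []
    for layer in layers:
        n_hidden = layer["bi"].shape[0]
        h = np.zeros((n, n_hidden))
        c = np.zeros((n, n_hidden))
        hs, layer_cache = [], []
        for t in range(t_len):
            z = np.concatenate([h, inputs[:, t, :]], axis=1)
            h, c, cache = lstm_cell(layer, z, c)
            hs.append(h)
            layer_cache.append(cache)
        inputs = np.stack(hs, axis=1)
        caches.append(layer_cache)
    y_hat = inputs[:, -1, :] @ readout["w"] + readout["b"]
    return y_hat, inputs, caches


def _backward(layers, readout, x, caches, top_h, dy):
    """Backpropagation through time for the stacked network."""
    n, t_len, _ = x.shape
    grads = [{k: np.zeros_like(v) for k, v in layer.items()}
             for layer in layers]
    g_read = {"w": top_h[:, -1, :].T @ dy, "b": float(dy.sum())}
    # gradient flowing into each layer's hidden outputs, per time step
    dh_above = [np.zeros((n, layer["bi"].shape[0]), dtype=float)
                for layer in layers]
    d_top = np.zeros((n, t_len, layers[-1]["bi"].shape[0]))
    d_top[:, -1, :] = dy[:, None] * readout["w"][None, :]
    d_from_above = d_top
    for li in range(len(layers) - 1, -1, -1):
        layer, grad = layers[li], grads[li]
        n_hidden = layer["bi"].shape[0]
        n_in = layer["wi"].shape[1] - n_hidden
        dx = np.zeros((n, t_len, n_in))
        dh_rec = np.zeros((n, n_hidden))
        dc_next = np.zeros((n, n_hidden))
        for t in range(t_len - 1, -1, -1):
            cache = caches[li][t]
            dh = d_from_above[:, t, :] + dh_rec
            do = dh * cache["tc"]
            dct = dh * cache["o"] * (1 - cache["tc"] ** 2) + dc_next
            df = dct * cache["c_prev"]
            di = dct * cache["g"]
            dg = dct * cache["i"]
            dc_next = dct * cache["f"]
            dai = di * cache["i"] * (1 - cache["i"])
            daf = df * cache["f"] * (1 - cache["f"])
            dao = do * cache["o"] * (1 - cache["o"])
            dag = dg * (1 - cache["g"] ** 2)
            z = cache["z"]
            grad["wi"] += dai.T @ z
            grad["wf"] += daf.T @ z
            grad["wo"] += dao.T @ z
            grad["wc"] += dag.T @ z
            grad["bi"] += dai.sum(axis=0)
            grad["bf"] += daf.sum(axis=0)
            grad["bo"] += dao.sum(axis=0)
            grad["bc"] += dag.sum(axis=0)
            dz = (dai @ layer["wi"] + daf @ layer["wf"]
                  + dao @ layer["wo"] + dag @ layer["wc"])
            dh_rec = dz[:, :n_hidden]
            dx[:, t, :] = dz[:, n_hidden:]
        d_from_above = dx
    return grads, g_read


class _Adam:
    def __init__(self, shapes, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        out = []
        for k, (p, g) in enumerate(zip(params, grads)):
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g ** 2
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))
        return out


def _flatten(layers, readout):
    params = []
    for layer in layers:
        params.extend(layer[g] for g in _GATES)
    params.append(readout["w"])
    params.append(np.array([readout["b"]]))
    return params


def _unflatten(params, n_layers):
    layers = []
    k = 0
    for _ in range(n_layers):
        layers.append({g: params[k + j] for j, g in enumerate(_GATES)})
        k += len(_GATES)
    readout = {"w": params[k], "b": float(params[k + 1][0])}
    return layers, readout


# ---------------------------------------------------------------------------
# estimator


class LSTMForecaster(BaseEstimator, RegressorMixin):
    """sklearn-style stacked-LSTM glucose forecaster.

    Attributes after :meth:`fit`: ``layers_`` (per-layer gate weights),
    ``readout_``, ``scaler_``, ``report_`` (held-out :class:`ForecastReport`)
    and ``loss_history_``.
    """

    def __init__(self, window: int = 8, horizon_nc: int = 4,
                 hidden_layers: int = 2, hidden_units: int = 32,
                 epochs: int = 200, train_fraction: float = 0.70,
                 excluded_interval=None, seed: int = 0,
                 learning_rate: float = 0.01, batch_size: int = 64,
                 patience: int = 20, scaling=None):
        self.window = window
        self.horizon_nc = horizon_nc
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.train_fraction = train_fraction
        self.excluded_interval = excluded_interval
        self.seed = seed
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.patience = patience
        self.scaling = scaling

    @property
    def config(self) -> ForecastConfig:
        return ForecastConfig(
            window=self.window, horizon_nc=self.horizon_nc,
            hidden_layers=self.hidden_layers, hidden_units=self.hidden_units,
            epochs=self.epochs, train_fraction=self.train_fraction,
            excluded_interval=(tuple(self.excluded_interval)
                               if self.excluded_interval else None),
            seed=self.seed, learning_rate=self.learning_rate,
            batch_size=self.batch_size, patience=self.patience,
            scaling=(tuple(map(tuple, self.scaling))
                     if self.scaling is not None else None))

    @classmethod
    def from_config(cls, config: ForecastConfig) -> "LSTMForecaster":
        return cls(**asdict(config))

    # -- training ----------------------------------------------------------

    def fit(self, series: GlucoseSeries, y=None):
        """Train on the chronological 70/30 split of one series."""
        cfg = self.config
        x_all, y_all, scaler = make_supervised(series, cfg)
        self.scaler_ = scaler
        n_train_samples = int(len(series) * cfg.train_fraction)
        target_idx = np.arange(cfg.window, len(series))
        is_train = target_idx < n_train_samples
        if cfg.excluded_interval is not None:
            lo, hi = cfg.excluded_interval
            t_target = series.t[target_idx]
            is_train &= ~((t_target >= lo) & (t_target <= hi))
        x_tr, y_tr = x_all[is_train], y_all[is_train]
        x_te, y_te = x_all[~is_train], y_all[~is_train]
        if len(x_tr) < 1:
            raise ValueError("not enough training pairs")

        rng = np.random.default_rng(cfg.seed)
        n_in = x_all.shape[2]
        layers = []
        for li in range(cfg.hidden_layers):
            layers.append(_init_layer(rng, n_in if li == 0 else
                                      cfg.hidden_units, cfg.hidden_units))
        readout = {"w": rng.uniform(-0.1, 0.1, size=cfg.hidden_units),
                   "b": 0.0}

        params = _flatten(layers, readout)
        adam = _Adam([p.shape for p in params], cfg.learning_rate)
        best_loss, best_params, since_best = np.inf, params, 0
        history = []
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(x_tr))
            for start in range(0, len(x_tr), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                layers, readout = _unflatten(params, cfg.hidden_layers)
                y_hat, top_h, caches = _forward(layers, readout, x_tr[sel])
                err = y_hat - y_tr[sel]
                if not np.all(np.isfinite(err)):
                    raise RuntimeError(
                        "training diverged: non-finite loss; lower the "
                        "learning rate or rescale the inputs")
                dy = 2.0 * err / len(sel)
                grads, g_read = _backward(layers, readout, x_tr[sel],
                                          caches, top_h, dy)
                flat_grads = []
                for grad in grads:
                    flat_grads.extend(grad[g] for g in _GATES)
                flat_grads.append(g_read["w"])
                flat_grads.append(np.array([g_read["b"]]))
                params = adam.step(params, flat_grads)
            layers, readout = _unflatten(params, cfg.hidden_layers)
            monitor_x = x_te if len(x_te) else x_tr
            monitor_y = y_te if len(x_te) else y_tr
            y_hat, _, _ = _forward(layers, readout, monitor_x)
            loss = float(np.mean((y_hat - monitor_y) ** 2))
            history.append(loss)
            if loss < best_loss - 1e-9:
                best_loss, best_params, since_best = loss, params, 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.layers_, self.readout_ = _unflatten(best_params,
                                                 cfg.hidden_layers)
        self.loss_history_ = np.asarray(history)
        self.report_ = (self._evaluate_pairs(x_te, y_te) if len(x_te)
                        else self._evaluate_pairs(x_tr, y_tr))
        return self

    # -- prediction --------------------------------------------------------

    def predict_scaled(self, x: np.ndarray) -> np.ndarray:
        """One-step predictions on already-scaled windows (N, window, 3)."""
        check_is_fitted(self, "layers_")
        y_hat, _, _ = _forward(self.layers_, self.readout_,
                               np.asarray(x, dtype=float))
        return y_hat

    def predict(self, x: np.ndarray) -> np.ndarray:
        """One-step predictions in mg/dL on raw windows (N, window, 3)."""
        x = np.asarray(x, dtype=float)
        scaled = self.scaler_.transform(x.reshape(-1, x.shape[2]))
        scaled = scaled.reshape(x.shape)
        return self.scaler_.inverse_glucose(self.predict_scaled(scaled))

    def forecast_recursive(self, history: np.ndarray, steps: int,
                           future_inputs: np.ndarray) -> np.ndarray:
        """Multi-step rollout feeding each prediction back as glucose input.

        ``history`` is the last ``window`` raw samples (window, 3);
        ``future_inputs`` the announced (insulin, cho) per step (steps, 2).
        Returns mg/dL forecasts of length ``steps``.
        """
        check_is_fitted(self, "layers_")
        if steps <= 0:
            raise ValueError("steps must be positive")
        history = np.asarray(history, dtype=float)
        if history.shape != (self.window, 3):
            raise ValueError(f"history must have shape ({self.window}, 3)")
        future_inputs = np.asarray(future_inputs, dtype=float)
        if future_inputs.shape[0] < steps:
            raise ValueError("future_inputs shorter than steps")
        win = self.scaler_.transform(history)
        out = np.empty(steps)
        for k in range(steps):
            y_scaled = float(self.predict_scaled(win[None])[0])
            out[k] = self.scaler_.inverse_glucose(y_scaled)
            nxt = self.scaler_.transform(
                np.array([[out[k], future_inputs[k, 0],
                           future_inputs[k, 1]]]))
            nxt[0, 0] = y_scaled
            win = np.vstack([win[1:], nxt])
        return out

    # -- evaluation --------------------------------------------------------

    def _evaluate_pairs(self, x, y) -> ForecastReport:
        y_hat = self.predict_scaled(x)
        rmse = float(np.sqrt(np.mean((y_hat - y) ** 2)))
        mae = float(np.mean(np.abs(y_hat - y)))
        y_raw = self.scaler_.inverse_glucose(y)
        y_hat_raw = self.scaler_.inverse_glucose(y_hat)
        ok = y_raw != 0
        n_excluded = int((~ok).sum())
        if n_excluded:
            warnings.warn(f"{n_excluded} zero-valued target(s) excluded "
                          "from percentage error", stacklevel=2)
        pct = float(np.mean(np.abs(y_raw[ok] - y_hat_raw[ok])
                            / np.abs(y_raw[ok])) * 100.0)
        return ForecastReport(pct_error=pct, rmse_norm=rmse, mae_norm=mae,
                              n_excluded=n_excluded)

    def evaluate(self, series: GlucoseSeries) -> ForecastReport:
        """One-step held-out style evaluation on a full series."""
        if len(series) <= self.window + 1:
            raise ValueError("series too short to evaluate")
        x, y, _ = make_supervised(series, self.config, scaler=self.scaler_)
        return self._evaluate_pairs(x, y)


# ---------------------------------------------------------------------------
# functional wrappers and persistence


def train(series: GlucoseSeries, config: ForecastConfig) -> LSTMForecaster:
    return LSTMForecaster.from_config(config).fit(series)


def evaluate(model: LSTMForecaster, series: GlucoseSeries) -> ForecastReport:
    return model.evaluate(series)


def forecast_recursive(model: LSTMForecaster, history, steps,
                       future_inputs) -> np.ndarray:
    return model.forecast_recursive(history, steps, future_inputs)


def save_json(model: LSTMForecaster, path) -> None:
    """Serialize weights, scaling and config to a JSON file."""
    check_is_fitted(model, "layers_")
    cfg = asdict(model.config)
    if cfg["excluded_interval"] is not None:
        cfg["excluded_interval"] = list(cfg["excluded_interval"])
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": cfg,
        "scaling": {"mins": model.scaler_.mins.tolist(),
                    "maxs": model.scaler_.maxs.tolist()},
        "layers": [{g: layer[g].tolist() for g in _GATES}
                   for layer in model.layers_],
        "readout": {"w": model.readout_["w"].tolist(),
                    "b": model.readout_["b"]},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_json(path) -> LSTMForecaster:
    """Load a model saved by :func:`save_json`.

    Raises
    ------
    ValueError
        On truncated files, unknown schema versions or missing fields.
    """
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is truncated or not valid "
                         f"JSON: {exc}") from exc
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version "
            f"{payload.get('schema_version')!r}; expected {SCHEMA_VERSION}")
    for key in ("config", "scaling", "layers", "readout"):
        if key not in payload:
            raise ValueError(f"model file missing field {key!r}")
    cfg = dict(payload["config"])
    if cfg.get("excluded_interval") is not None:
        cfg["excluded_interval"] = tuple(cfg["excluded_interval"])
    model = LSTMForecaster(**cfg)
    model.scaler_ = _Scaler(payload["scaling"]["mins"],
                            payload["scaling"]["maxs"])
    model.layers_ = [{g: np.asarray(layer[g], dtype=float) for g in _GATES}
                     for layer in payload["layers"]]
    model.readout_ = {"w": np.asarray(payload["readout"]["w"], dtype=float),
                      "b": float(payload["readout"]["b"])}
    return model
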