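"""Personalized adaptive glucose model via recursive least squares.

The patient model is the linear one-step recursion

    G(k+1) = z1·G(k) + z2·I(k) + z3·CHO(k) + eps(k)

with parameter vector ``w = (z1, z2, z3)`` estimated online by exponentially
weighted recursive least squares (RLS) with forgetting factor ``lam``: at
each epoch the estimator minimizes the lam-discounted sum of squared
one-step residuals, weighted by a positive scalar observation weight.  The
forgetting factor lets the estimate track slow drifts in insulin
sensitivity or carbohydrate response.  An optional dead zone skips the
update when the innovation is smaller than a tolerance, and an optional
sign projection keeps the estimate physiological (z2 <= 0, z3 >= 0,
z1 in [0, 1.2]) when the model feeds the controller.

Both a functional interface over an immutable :class:`AdaptiveModelState`
and an sklearn-style estimator (:class:`RecursiveGlucoseModel`) are
provided; the estimator is a thin wrapper over the functional core.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .series import GlucoseSeries

_Z1_MAX = 1.2   # projection ceiling for glucose persistence
#: physiological magnitude bounds completing the sign projection: no
#: patient drops more than 10 mg/dL per unit per epoch, nor rises more
#: than 1 mg/dL per gram.  Projection onto a known parameter region keeps
#: the estimate recoverable when closed-loop data are barely exciting
#: (between meals, glucose and insulin are both nearly constant, leaving a
#: collinear direction along which the estimate would otherwise drift).
_Z2_MIN = -10.0
_Z3_MAX = 1.0


@dataclass(frozen=True)
class AdaptiveModelState:
    """Immutable RLS state: parameters, inverse-correlation matrix, knobs.

    ``p_matrix`` is the (scaled) inverse correlation matrix of the
    regressors; its trace shrinks as data accumulates.  ``obs_weight`` is a
    positive scalar weight on each observation; ``noise_bound`` is a stated
    bound on the disturbance norm, stored for residual diagnostics only.
    """

    w: np.ndarray
    p_matrix: np.ndarray
    lam: float = 0.98
    obs_weight: float = 1.0
    dead_zone: float = 0.0
    noise_bound: float | None = None
    sign_projection: bool = False
    #: covariance-limiting ceiling on trace(p_matrix); ``None`` disables.
    #: Forgetting inflates the p_matrix without bound along unexcited
    #: directions (classic windup); capping the trace at the prior's says
    #: the estimator never becomes more uncertain than it started.
    p_trace_max: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=float))
        object.__setattr__(self, "p_matrix",
                           np.asarray(self.p_matrix, dtype=float))
        if not (0 < self.lam <= 1):
            raise ValueError("forgetting factor must lie in (0, 1]")
        if self.obs_weight <= 0:
            raise ValueError("observation weight must be positive")
        if self.dead_zone < 0:
            raise ValueError("dead zone must be non-negative")
        if self.p_matrix.shape != (len(self.w), len(self.w)):
            raise ValueError("p_matrix shape does not match w")
        if not np.allclose(self.p_matrix, self.p_matrix.T, atol=1e-8):
            raise ValueError("p_matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(self.p_matrix) <= 0):
            raise ValueError("p_matrix must be positive definite")


def initial_state(init_w=(0.9, -0.5, 0.1), init_p_scale=1e3,
                  **kwargs) -> AdaptiveModelState:
    """Weakly informative starting state (large p_matrix, plausible w).

    ``init_p_scale`` may be a scalar (isotropic prior) or a length-3
    sequence of per-coordinate prior scales; the latter matters in closed
    loop, where the glucose regressor is two orders of magnitude larger
    than the insulin one and an isotropic prior leaves the insulin
    coefficient nearly unconstrained.
    """
    w = np.asarray(init_w, dtype=float)
    scale = np.asarray(init_p_scale, dtype=float)
    p = (scale * np.eye(len(w)) if scale.ndim == 0
         else np.diag(scale))
    return AdaptiveModelState(w=w, p_matrix=p, **kwargs)


def predict_one_step(state: AdaptiveModelState, h) -> float:
    """Model prediction h·w for regressors h = (G, I, CHO)."""
    h = np.asarray(h, dtype=float)
    return float(h @ state.w)


def _project(w: np.ndarray) -> np.ndarray:
    w = w.copy()
    w[0] = np.clip(w[0], 0.0, _Z1_MAX)
    w[1] = np.clip(w[1], _Z2_MIN, 0.0)
    w[2] = np.clip(w[2], 0.0, _Z3_MAX)
    return w


def rls_update(state: AdaptiveModelState, h, g_next: float,
               ) -> AdaptiveModelState:
    """One forgetting-factor RLS step; returns the new state.

    Skips the update (parameters kept as previous) when the innovation
    magnitude is within the dead zone.  Raises if the gain denominator is
    non-finite or non-positive, which would indicate a corrupted state
    rather than a condition to clamp silently.
    """
    h = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("regressors must be finite")
    innovation = float(g_next) - float(h @ state.w)
    if abs(innovation) <= state.dead_zone:
        return state
    ph = state.p_matrix @ h
    denom = state.lam / state.obs_weight + float(h @ ph)
    if not np.isfinite(denom) or denom <= 0:
        raise ArithmeticError("RLS gain denominator is not positive finite; "
                              "state is rank-deficient or corrupted")
    gain = ph / denom
    w_new = state.w + gain * innovation
    p_new = (state.p_matrix - np.outer(gain, ph)) / state.lam
    p_new = 0.5 * (p_new + p_new.T)  # keep symmetry against roundoff
    if state.p_trace_max is not None:
        tr = float(np.trace(p_new))
        if tr > state.p_trace_max:
            p_new *= state.p_trace_max / tr
    if state.sign_projection:
        w_new = _project(w_new)
    return replace(state, w=w_new, p_matrix=p_new)


def save_state(state: AdaptiveModelState, path) -> None:
    """Serialize an estimator state to a key-value text file."""
    lines = [
        f"w = {' '.join(repr(float(v)) for v in state.w)}",
        "p_matrix = " + " ".join(repr(float(v))
                                 for v in state.p_matrix.ravel()),
        f"lam = {state.lam!r}",
        f"obs_weight = {state.obs_weight!r}",
        f"dead_zone = {state.dead_zone!r}",
        f"noise_bound = {state.noise_bound!r}",
        f"sign_projection = {state.sign_projection}",
        f"p_trace_max = {state.p_trace_max!r}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_state(path) -> AdaptiveModelState:
    """Read a state written by :func:`save_state`."""
    fields: dict = {}
    with open(path) as fh:
        for line in fh:
            if "=" not in line:
                continue
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    w = np.array([float(v) for v in fields["w"].split()])
    k = len(w)
    p = np.array([float(v) for v in
                  fields["p_matrix"].split()]).reshape(k, k)
    opt = {}
    for name, cast in (("lam", float), ("obs_weight", float),
                       ("dead_zone", float), ("noise_bound", float),
                       ("p_trace_max", float)):
        raw = fields.get(name, "None")
        opt[name] = None if raw == "None" else cast(raw)
    opt["lam"] = opt["lam"] if opt["lam"] is not None else 0.98
    opt["obs_weight"] = opt["obs_weight"] or 1.0
    opt["dead_zone"] = opt["dead_zone"] or 0.0
    return AdaptiveModelState(
        w=w, p_matrix=p,
        sign_projection=fields.get("sign_projection") == "True", **opt)


@dataclass
class FitReport:
    """Sequential predict-then-update pass over a series."""

    w_trajectory: np.ndarray  # (n_transitions, 3)
    residuals: np.ndarray     # one-step innovations G(k+1) - h(k)·w(k)
    rmse: float
    final_state: AdaptiveModelState

    def to_csv(self, path) -> None:
        """Write (epoch, z1, z2, z3, residual) rows."""
        import pandas as pd
        pd.DataFrame({
            "epoch": np.arange(len(self.residuals)),
            "z1": self.w_trajectory[:, 0],
            "z2": self.w_trajectory[:, 1],
            "z3": self.w_trajectory[:, 2],
            "residual": self.residuals,
        }).to_csv(path, index=False)


def fit_series(series: GlucoseSeries, lam: float = 0.98,
               init_w=(0.9, -0.5, 0.1), init_p_scale: float = 1e3,
               dead_zone: float = 0.0, obs_weight: float = 1.0,
               sign_projection: bool = False) -> FitReport:
    """Run the recursive estimator over a series, predicting each next BGL.

    At each valid transition the current parameters predict G(k+1) from
    (G(k), I(k), CHO(k)); the residual is recorded before the parameters
    are updated with the realized measurement.  Gaps must be imputed first
    (see :mod:`glytwin.diagnostics`).
    """
    if int(series.mask.sum()) < 4:
        raise ValueError("need at least 4 valid samples")
    if not series.mask.all():
        raise ValueError("series has gaps; impute before fitting")
    state = initial_state(init_w, init_p_scale, lam=lam,
                          dead_zone=dead_zone, obs_weight=obs_weight,
                          sign_projection=sign_projection)
    n = len(series) - 1
    w_traj = np.empty((n, len(state.w)))
    resid = np.empty(n)
    for k in range(n):
        h = np.array([series.bgl[k], series.insulin[k], series.cho[k]])
        resid[k] = series.bgl[k + 1] - predict_one_step(state, h)
        state = rls_update(state, h, series.bgl[k + 1])
        w_traj[k] = state.w
    return FitReport(w_trajectory=w_traj, residuals=resid,
                     rmse=float(np.sqrt(np.mean(resid ** 2))),
                     final_state=state)


class RecursiveGlucoseModel(BaseEstimator, RegressorMixin):
    """sklearn-style wrapper around the forgetting-factor RLS estimator.

    Parameters
    ----------
    lam : float
        Forgetting factor in (0, 1]; 1 means ordinary least squares.
    dead_zone : float
        Innovation magnitude below which no update happens (mg/dL).
    obs_weight : float
        Positive scalar weight on each observation.
    init_w, init_p_scale :
        Starting parameter vector and p-matrix scale.
    sign_projection : bool
        Clip the estimate to the physiological orthant after each update.

    Attributes
    ----------
    w_ : ndarray of shape (3,)
        Current parameter estimate (z1, z2, z3).
    p_matrix_ : ndarray of shape (3, 3)
        Inverse-correlation matrix.
    n_updates_ : int
        Number of RLS updates applied.
    """

    def __init__(self, lam: float = 0.98, dead_zone: float = 0.0,
                 obs_weight: float = 1.0, init_w=(0.9, -0.5, 0.1),
                 init_p_scale: float = 1e3, sign_projection: bool = False):
        self.lam = lam
        self.dead_zone = dead_zone
        self.obs_weight = obs_weight
        self.init_w = init_w
        self.init_p_scale = init_p_scale
        self.sign_projection = sign_projection

    def _init_state(self) -> AdaptiveModelState:
        return initial_state(self.init_w, self.init_p_scale, lam=self.lam,
                             dead_zone=self.dead_zone,
                             obs_weight=self.obs_weight,
                             sign_projection=self.sign_projection)

    @property
    def state_(self) -> AdaptiveModelState:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "w_")
        return AdaptiveModelState(
            w=self.w_, p_matrix=self.p_matrix_, lam=self.lam,
            dead_zone=self.dead_zone, obs_weight=self.obs_weight,
            sign_projection=self.sign_projection)

    def fit(self, X, y):
        """Sequentially fit regressor rows X = (G, I, CHO) to targets y."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one row per target")
        state = self._init_state()
        self.w_ = state.w
        self.p_matrix_ = state.p_matrix
        self.n_updates_ = 0
        return self.partial_fit(X, y)

    def partial_fit(self, X, y):
        """Continue fitting from the current state (online use)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        if not hasattr(self, "w_"):
            state = self._init_state()
        else:
            state = AdaptiveModelState(
                w=self.w_, p_matrix=self.p_matrix_, lam=self.lam,
                dead_zone=self.dead_zone, obs_weight=self.obs_weight,
                sign_projection=self.sign_projection)
            if not hasattr(self, "n_updates_"):
                self.n_updates_ = 0
        for h, target in zip(X, y):
            state = rls_update(state, h, float(target))
        self.w_ = state.w
        self.p_matrix_ = state.p_matrix
        self.n_updates_ = getattr(self, "n_updates_", 0) + len(y)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "w_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.w_


def batch_weighted_ls(X, y, lam: float, init_w, init_p_scale: float,
                      obs_weight: float = 1.0) -> np.ndarray:
    """Closed-form minimizer of the exponentially weighted criterion.

    Solves the same regularized problem the recursive update solves:
    lam-discounted weighted squared residuals plus the prior term
    lam**N (w - w0)' P0^{-1} (w - w0) induced by the initial p_matrix.
    Used as the independent oracle for the recursion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w0 = np.asarray(init_w, dtype=float)
    p0_inv = np.eye(len(w0)) / init_p_scale
    weights = obs_weight * lam ** (n - 1 - np.arange(n))
    a = lam ** n * p0_inv + (X.T * weights) @ X
    b = lam ** n * p0_inv @ w0 + (X.T * weights) @ y
    return np.linalg.solve(a, b)
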