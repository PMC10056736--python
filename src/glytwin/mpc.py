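"""Learning-based model predictive insulin controller.

Each epoch the controller solves a receding-horizon linear program over the
next ``np_horizon`` 15-minute steps:

    min   sum_k  c_t·I(k) + c_gamma·gamma(k)
    s.t.  G(k+1) = (z1 + da(k))·G(k) + z2·I(k) + (z3 + dc)·CHO(k) + eps1
          g_min − gamma(k) <= G(k) <= g_max + gamma(k)
          i_min <= I(k) <= i_max,   gamma(k) >= 0

where ``eps1`` is the latest one-step model residual (a static disturbance
estimate, held constant over the horizon) and ``da(k)`` is a small
multiplicative perturbation of the glucose-persistence parameter fusing the
LSTM forecast with the model estimate:

    da = eta1 · yhat(k+1)/Ghat(k+1) + eta2 · (yhat(k+1) − yhat(k))/h

with sampling time ``h`` minutes.  When forecast and model agree and the
forecast is flat, ``da ≈ eta1 > 0``: the controller deliberately
over-predicts glucose persistence, which in closed loop settles the patient
a safety margin of roughly ``eta1·g_max`` below the band ceiling — the
mechanism by which the learned term encodes conservative dosing for
geriatric patients.  Slack variables make the band constraint soft, so the
program is always feasible; insulin bounds are hard.  The objective is
linear, so the solve is a single HiGHS linear program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .adaptive_model import AdaptiveModelState


@dataclass(frozen=True)
class MPCConfig:
    """Controller tuning; defaults follow the trial setup (Np=4, Ts=15)."""

    np_horizon: int = 4
    ts: float = 15.0
    g_min: float = 70.0
    g_max: float = 180.0
    i_min: float = 0.0
    i_max: float = 2.5
    c_t: float = 1.0
    c_gamma: float = 1e4
    eta1: float = 0.05
    eta2: float = 0.05
    delta_c: float = 0.0
    perturbation_variant: str = "literal"  # or "ratio_minus_one"

    def __post_init__(self) -> None:
        if self.np_horizon < 1:
            raise ValueError("np_horizon must be at least 1")
        if not (self.g_min < self.g_max):
            raise ValueError("glucose band must satisfy g_min < g_max")
        if not (0 <= self.i_min < self.i_max):
            raise ValueError("insulin bounds must satisfy 0 <= i_min < i_max")
        if self.c_gamma < 100 * self.c_t:
            raise ValueError("slack cost must dominate: c_gamma >= 100*c_t")
        if not (0 < self.eta1 < 1) or not (0 < self.eta2 < 1):
            raise ValueError("adaptation parameters must lie in (0, 1)")
        if self.perturbation_variant not in ("literal", "ratio_minus_one"):
            raise ValueError(
                f"unknown perturbation variant {self.perturbation_variant!r}")


@dataclass
class InsulinPlan:
    """Receding-horizon solution; only ``insulin[0]`` is ever applied."""

    insulin: np.ndarray
    slack: np.ndarray
    predicted_g: np.ndarray
    delta_a: np.ndarray
    eps1: float
    objective: float
    status: str  # optimal | infeasible_soft | error
    message: str = ""


def compute_disturbance(w, g_next: float, h) -> float:
    """Static disturbance: realized G(k+1) minus the model's prediction."""
    w = np.asarray(w, dtype=float)
    h = np.asarray(h, dtype=float)
    return float(g_next) - float(h @ w)


def compute_perturbation(eta1: float, eta2: float, ts: float,
                         y_hat_next: float, y_hat_now: float,
                         g_model_next: float,
                         variant: str = "literal") -> float:
    """Forecast-driven perturbation of the glucose-persistence parameter.

    ``variant="literal"`` evaluates the published form directly (the first
    term is a ratio, approx 1 when forecast and model agree);
    ``"ratio_minus_one"`` replaces the ratio with its deviation from 1, so
    agreement yields zero perturbation.  The two are never mixed in a run.
    """
    if g_model_next <= 0:
        raise ValueError("model glucose estimate must be positive")
    ratio = y_hat_next / g_model_next
    if variant == "ratio_minus_one":
        ratio -= 1.0
    elif variant != "literal":
        raise ValueError(f"unknown perturbation variant {variant!r}")
    slope = (y_hat_next - y_hat_now) / ts
    return eta1 * ratio + eta2 * slope


def _horizon_perturbations(state: AdaptiveModelState, config: MPCConfig,
                           g_now: float, cho_forecast: np.ndarray,
                           y_hat: np.ndarray | None, eps1: float,
                           y_hat_now: float | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step delta_a plus the nominal model-propagated glucose.

    The model estimate Ghat is propagated with zero insulin and announced
    CHO (it cannot depend on the insulin decision without making the
    program nonlinear); each step's delta_a then fuses Ghat with the
    corresponding forecast samples.  ``y_hat_now`` is the forecaster's
    one-step estimate of the *current* sample: the slope term differences
    consecutive forecaster outputs, so a constant forecaster bias cancels
    instead of masquerading as a glucose trend.  When unavailable the
    current measurement stands in.
    """
    npz = config.np_horizon
    z1, z2, z3 = state.w
    delta_a = np.zeros(npz)
    g_nominal = np.empty(npz)
    g = float(g_now)
    y_prev = float(g_now) if y_hat_now is None else float(y_hat_now)
    for k in range(npz):
        g = z1 * g + z3 * cho_forecast[k] + eps1
        g = max(g, 1.0)  # keep the ratio well-defined under model error
        g_nominal[k] = g
        if y_hat is not None:
            delta_a[k] = compute_perturbation(
                config.eta1, config.eta2, config.ts,
                float(y_hat[k]), y_prev, g,
                variant=config.perturbation_variant)
            y_prev = float(y_hat[k])
    return delta_a, g_nominal


def solve_mpc(state: AdaptiveModelState, config: MPCConfig, g_now: float,
              cho_forecast, y_hat=None, eps1: float = 0.0,
              delta_a=None, y_hat_now: float | None = None) -> InsulinPlan:
    """Solve the soft-constrained receding-horizon linear program.

    ``cho_forecast`` holds the announced carbohydrates per step; ``y_hat``
    the forecaster's glucose trajectory over the horizon (``None`` disables
    the perturbation, ``delta_a`` overrides it).  Decision variables are
    the insulin doses and per-step slacks; predicted glucose is affine in
    insulin, so band constraints become linear inequalities.
    """
    npz = config.np_horizon
    cho_forecast = np.asarray(cho_forecast, dtype=float)[:npz]
    if len(cho_forecast) < npz:
        raise ValueError("cho_forecast shorter than the horizon")
    if y_hat is not None:
        y_hat = np.asarray(y_hat, dtype=float)
        if len(y_hat) < npz:
            raise ValueError("y_hat shorter than the horizon")
    if delta_a is None:
        delta_a, _ = _horizon_perturbations(state, config, g_now,
                                            cho_forecast, y_hat, eps1,
                                            y_hat_now=y_hat_now)
    else:
        delta_a = np.asarray(delta_a, dtype=float)[:npz]
    z1, z2, z3 = state.w
    a = z1 + delta_a  # per-step effective persistence

    # G_j = base_j + sum_m M[j, m] * I_m   (affine propagation)
    base = np.empty(npz)
    m_ins = np.zeros((npz, npz))
    prev_base = float(g_now)
    for j in range(npz):
        base[j] = a[j] * prev_base + (z3 + config.delta_c) * cho_forecast[j] \
            + eps1
        if j > 0:
            m_ins[j, :j] = a[j] * m_ins[j - 1, :j]
        m_ins[j, j] = z2
        prev_base = base[j]

    # variables x = [I_1..I_Np, gamma_1..gamma_Np]
    c = np.concatenate([np.full(npz, config.c_t),
                        np.full(npz, config.c_gamma)])
    # G_j - gamma_j <= g_max  and  -G_j - gamma_j <= -g_min
    a_ub = np.block([[m_ins, -np.eye(npz)],
                     [-m_ins, -np.eye(npz)]])
    b_ub = np.concatenate([config.g_max - base, base - config.g_min])
    bounds = [(config.i_min, config.i_max)] * npz + [(0.0, None)] * npz

    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": 1e-9,
                           "dual_feasibility_tolerance": 1e-9})
    if not res.success:
        # slack makes the program totally feasible; reaching here means a
        # solver failure, reported rather than silently patched
        status = "infeasible_soft" if res.status == 2 else "error"
        return InsulinPlan(insulin=np.full(npz, config.i_min),
                           slack=np.zeros(npz), predicted_g=base,
                           delta_a=delta_a, eps1=eps1, objective=np.inf,
                           status=status, message=str(res.message))
    insulin = np.clip(res.x[:npz], config.i_min, config.i_max)
    slack = np.maximum(res.x[npz:], 0.0)
    predicted = base + m_ins @ insulin
    return InsulinPlan(insulin=insulin, slack=slack, predicted_g=predicted,
                       delta_a=delta_a, eps1=eps1,
                       objective=float(res.fun), status="optimal")


def control_step(state: AdaptiveModelState, config: MPCConfig,
                 measurement: float, history, forecaster,
                 announced_cho) -> tuple[float, InsulinPlan]:
    """One receding-horizon decision; returns (applied dose, full plan).

    ``history`` is a :class:`~glytwin.series.GlucoseSeries` ending at the
    current epoch (used for the forecaster window and the latest residual);
    ``announced_cho`` the carbohydrates announced over the horizon.  If no
    forecaster is available the perturbation degrades to zero with a
    warning.
    """
    announced_cho = np.asarray(announced_cho, dtype=float)
    n = len(history)
    if n >= 2:
        h_prev = np.array([history.bgl[n - 2], history.insulin[n - 2],
                           history.cho[n - 2]])
        eps1 = compute_disturbance(state.w, history.bgl[n - 1], h_prev)
    else:
        eps1 = 0.0

    y_hat = None
    y_hat_now = None
    if forecaster is not None:
        window = forecaster.window
        if n >= window + 1:
            hist = np.column_stack([history.bgl[n - window:],
                                    history.insulin[n - window:],
                                    history.cho[n - window:]])
            future = np.column_stack([
                np.full(config.np_horizon, history.insulin[n - 1]),
                announced_cho[:config.np_horizon]])
            y_hat = forecaster.forecast_recursive(hist, config.np_horizon,
                                                  future)
            # one-step estimate of the current sample, so the slope term
            # compares forecaster output against forecaster output
            prev = np.column_stack([history.bgl[n - window - 1:n - 1],
                                    history.insulin[n - window - 1:n - 1],
                                    history.cho[n - window - 1:n - 1]])
            y_hat_now = float(forecaster.predict(prev[None])[0])
    if forecaster is not None and y_hat is None:
        warnings.warn("history shorter than the forecaster window; "
                      "running with zero perturbation", stacklevel=2)

    plan = solve_mpc(state, config, measurement, announced_cho,
                     y_hat=y_hat, eps1=eps1, y_hat_now=y_hat_now)
    return float(plan.insulin[0]), plan
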