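"""CGM time-series diagnostics: imputation, correlograms, matrix profile,
and structural (unobserved-components) decomposition.

The matrix profile stores, for every length-``m`` subsequence of a series,
the Euclidean distance to its nearest non-trivial neighbour; minima mark
motifs (recurring patterns, e.g. post-prandial responses with similar
carbohydrate loads), maxima mark discords (anomalies, e.g. sensor faults or
atypical days).  Both raw-Euclidean and z-normalized subsequence distances
are supported, and day-to-day distances are reported raw and per-sample
normalized because the clinically meaningful scale depends on the window
length.  The profile is computed by an exact vectorized scan of all window
pairs, which is ample at 14-day CGM scale.

The structural decomposition splits a series additively into local linear
trend, daily seasonal (period 96 at 15-min sampling), optional cycle and
regression effects, plus an irregular remainder, estimated by maximum
likelihood with a Kalman filter/smoother (statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from statsmodels.tsa.stattools import acf as _sm_acf, pacf as _sm_pacf
from statsmodels.tsa.statespace.structural import UnobservedComponents

from .series import GlucoseSeries

# ---------------------------------------------------------------------------
# imputation and correlograms


def impute(series: GlucoseSeries, method: str = "previous") -> GlucoseSeries:
    """Fill invalid glucose samples; the input series is left untouched.

    ``mean`` fills with the mean of valid samples; ``previous``/``next``
    carry the nearest valid sample forward/backward.  A leading gap under
    ``previous`` (or trailing gap under ``next``) falls back to the nearest
    valid sample on the other side, with a warning.
    """
    if not series.mask.any():
        raise ValueError("series has no valid samples")
    if method not in ("mean", "previous", "next"):
        raise ValueError(f"unknown imputation method {method!r}")
    out = series.copy()
    bgl = out.bgl
    valid_idx = np.flatnonzero(out.mask)
    if method == "mean":
        bgl[~out.mask] = bgl[out.mask].mean()
    else:
        import warnings
        if method == "previous" and not out.mask[0]:
            warnings.warn("leading gap: falling back to next valid sample",
                          stacklevel=2)
        if method == "next" and not out.mask[-1]:
            warnings.warn("trailing gap: falling back to previous valid "
                          "sample", stacklevel=2)
        side = "right" if method == "previous" else "left"
        pos = np.searchsorted(valid_idx, np.arange(len(bgl)), side=side)
        if method == "previous":
            pos = np.clip(pos - 1, 0, len(valid_idx) - 1)
        else:
            pos = np.clip(pos, 0, len(valid_idx) - 1)
        fill = bgl[valid_idx[pos]]
        bgl[~out.mask] = fill[~out.mask]
    out.mask[:] = True
    return out


def acf_pacf(series: GlucoseSeries, max_lag: int,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Sample ACF and Durbin–Levinson PACF of the glucose channel.

    Lag-0 entries are both 1.  Raises on constant input, where the
    correlations are undefined.
    """
    x = series.bgl[series.mask]
    if len(x) < max_lag + 2:
        raise ValueError("need at least max_lag + 2 valid samples")
    if np.ptp(x) == 0:
        raise ValueError("correlations undefined for a constant series")
    acf_vals = _sm_acf(x, nlags=max_lag, fft=True)
    pacf_vals = _sm_pacf(x, nlags=max_lag, method="ld")
    return acf_vals, pacf_vals


# ---------------------------------------------------------------------------
# matrix profile


@dataclass
class MatrixProfileResult:
    """Nearest-neighbour distance per subsequence and where it points."""

    profile: np.ndarray
    index: np.ndarray
    m: int
    mode: str            # self_join | ab_join
    normalized: bool


def _windows(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n_sub = len(x) - m + 1
    idx = np.arange(n_sub)[:, None] + np.arange(m)[None, :]
    return x[idx]


def _znorm(w: np.ndarray) -> np.ndarray:
    mu = w.mean(axis=1, keepdims=True)
    sd = w.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (w - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return out  # constant windows map to the zero vector by convention


def matrix_profile_self(x, m: int, normalized: bool = False,
                        ) -> MatrixProfileResult:
    """Self-join matrix profile with exclusion zone ceil(m/2)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2 * m:
        raise ValueError("series must be at least twice the window length")
    w = _windows(x, m)
    if normalized:
        w = _znorm(w)
    d = cdist(w, w)
    excl = int(np.ceil(m / 2))
    n_sub = len(w)
    for i in range(n_sub):
        lo, hi = max(0, i - excl), min(n_sub, i + excl + 1)
        d[i, lo:hi] = np.inf
    index = d.argmin(axis=1)
    profile = d[np.arange(n_sub), index]
    return MatrixProfileResult(profile=profile, index=index, m=m,
                               mode="self_join", normalized=normalized)


def matrix_profile_join(a, b, m: int, normalized: bool = False,
                        ) -> MatrixProfileResult:
    """AB-join: for each window of ``a``, nearest window of ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < m or len(b) < m:
        raise ValueError("both series must be at least the window length")
    wa, wb = _windows(a, m), _windows(b, m)
    if normalized:
        wa, wb = _znorm(wa), _znorm(wb)
    d = cdist(wa, wb)
    index = d.argmin(axis=1)
    profile = d[np.arange(len(wa)), index]
    return MatrixProfileResult(profile=profile, index=index, m=m,
                               mode="ab_join", normalized=normalized)


def top_motif(result: MatrixProfileResult,
              ) -> tuple[tuple[int, int], float]:
    """Most similar subsequence pair; ties break to the earliest position."""
    i = int(result.profile.argmin())  # argmin returns the first minimum
    return (i, int(result.index[i])), float(result.profile[i])


def top_discord(result: MatrixProfileResult) -> tuple[int, float]:
    """Most anomalous subsequence; ties break to the earliest position."""
    finite = np.where(np.isfinite(result.profile), result.profile, -np.inf)
    i = int(finite.argmax())
    return i, float(result.profile[i])


def day_distance(series: GlucoseSeries, day_i: int, day_j: int,
                 m: int = 96) -> tuple[float, float]:
    """Euclidean distance between two day-long glucose subsequences.

    Returns ``(raw, per_sample)`` where ``per_sample = raw / sqrt(m)``;
    both days must be complete and fully valid.
    """
    di, dj = series.day(day_i), series.day(day_j)
    if not (di.mask.all() and dj.mask.all()):
        raise ValueError("both days must be fully valid")
    if len(di) < m or len(dj) < m:
        raise ValueError("day shorter than the requested window")
    raw = float(np.linalg.norm(di.bgl[:m] - dj.bgl[:m]))
    return raw, raw / np.sqrt(m)


# ---------------------------------------------------------------------------
# structural decomposition


@dataclass
class UCMDecomposition:
    """Additive components of the fitted series (all in mg/dL).

    ``trend + seasonal + cycle + regression_effects + irregular``
    reconstructs the observed series exactly; ``irregular`` is the smoothed
    remainder.  ``component_variances`` holds the ML-estimated state and
    observation variances, keyed by statsmodels parameter name.
    """

    trend: np.ndarray
    seasonal: np.ndarray
    cycle: np.ndarray
    regression_effects: np.ndarray
    irregular: np.ndarray
    component_variances: dict
    log_likelihood: float
    converged: bool


def fit_ucm(series: GlucoseSeries, period: int = 96,
            with_cycle: bool = False, regressors=None,
            ) -> UCMDecomposition:
    """Maximum-likelihood structural decomposition of the glucose channel.

    Local linear trend plus a dummy seasonal of the given period (96 = one
    day of 15-min epochs); the cycle component is off by default.  Requires
    at least three full periods so the seasonal is identified.  A
    non-converged likelihood maximization is reported through the
    ``converged`` flag rather than raised, with the last iterate returned.
    """
    y = series.bgl
    if not series.mask.all():
        raise ValueError("series has gaps; impute before decomposition")
    if len(y) < 3 * period:
        raise ValueError("need at least three full periods of data")
    model = UnobservedComponents(
        y, level="local linear trend", seasonal=period,
        cycle=with_cycle, stochastic_cycle=with_cycle,
        exog=np.asarray(regressors, dtype=float) if regressors is not None
        else None)
    with np.errstate(all="ignore"):
        fitted = model.fit(disp=0, maxiter=200)
    n = len(y)
    trend = np.asarray(fitted.level.smoothed)
    seasonal = np.asarray(fitted.seasonal.smoothed)
    cycle = (np.asarray(fitted.cycle.smoothed) if with_cycle
             else np.zeros(n))
    if regressors is not None:
        exog = np.atleast_2d(np.asarray(regressors, dtype=float))
        if exog.shape[0] != n:
            exog = exog.T
        beta = np.array([fitted.params[k] for k, name in
                         enumerate(fitted.param_names)
                         if name.startswith("beta")])
        reg = exog @ beta
    else:
        reg = np.zeros(n)
    irregular = y - trend - seasonal - cycle - reg
    variances = {name: float(val) for name, val in
                 zip(fitted.param_names, fitted.params)
                 if name.startswith("sigma2")}
    return UCMDecomposition(
        trend=trend, seasonal=seasonal, cycle=cycle,
        regression_effects=reg, irregular=irregular,
        component_variances=variances,
        log_likelihood=float(fitted.llf),
        converged=bool(fitted.mle_retvals.get("converged", True)))
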