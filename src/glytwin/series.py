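"""Uniform-grid CGM record: glucose, insulin and carbohydrate channels.

:class:`GlucoseSeries` is the exchange object every module consumes and
produces: a 15-minute (default) grid of blood glucose (mg/dL), delivered
insulin (units per epoch) and carbohydrate intake (grams per epoch), plus a
per-sample validity mask for the glucose channel.  It round-trips losslessly
to delimited text with header ``t_min,bgl_mgdl,insulin_U,cho_g,valid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical CSV header, one column per field
CSV_COLUMNS = ["t_min", "bgl_mgdl", "insulin_U", "cho_g", "valid"]

#: default sampling interval in minutes
DEFAULT_DT_MIN = 15.0

#: samples per day at the default interval
EPOCHS_PER_DAY = 96


@dataclass
class GlucoseSeries:
    """Multichannel CGM-style record on a uniform time grid.

    Parameters
    ----------
    t : ndarray
        Minutes since start; strictly increasing, constant spacing.
    bgl : ndarray
        Blood glucose in mg/dL.  Entries where ``mask`` is False are
        placeholders (NaN allowed) and excluded from computations.
    insulin : ndarray
        Insulin delivered during each epoch, in units.
    cho : ndarray
        Carbohydrate intake during each epoch, in grams.
    mask : ndarray of bool
        Validity of each glucose sample.
    """

    t: np.ndarray
    bgl: np.ndarray
    insulin: np.ndarray
    cho: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bgl = np.asarray(self.bgl, dtype=float)
        self.insulin = np.asarray(self.insulin, dtype=float)
        self.cho = np.asarray(self.cho, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.bgl)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.t)
        for name in ("bgl", "insulin", "cho", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if n >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0]):
                raise ValueError("time grid is not uniform")
            if dt[0] <= 0:
                raise ValueError("time grid must be increasing")
        if np.any(self.bgl[self.mask] <= 0):
            raise ValueError("valid glucose samples must be positive")
        if np.any(self.insulin < 0) or np.any(self.cho < 0):
            raise ValueError("insulin and cho must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_min(self) -> float:
        """Grid spacing in minutes."""
        if len(self.t) < 2:
            return DEFAULT_DT_MIN
        return float(self.t[1] - self.t[0])

    @property
    def epochs_per_day(self) -> int:
        return int(round(24 * 60 / self.dt_min))

    @property
    def n_days(self) -> int:
        return len(self) // self.epochs_per_day

    def copy(self) -> "GlucoseSeries":
        return GlucoseSeries(self.t.copy(), self.bgl.copy(),
                             self.insulin.copy(), self.cho.copy(),
                             self.mask.copy())

    def slice(self, start: int, stop: int | None = None) -> "GlucoseSeries":
        """Sub-series by sample index (time stamps preserved)."""
        sl = np.s_[start:stop]
        return GlucoseSeries(self.t[sl], self.bgl[sl], self.insulin[sl],
                             self.cho[sl], self.mask[sl])

    def day(self, i: int) -> "GlucoseSeries":
        """The ``i``-th full day (0-based)."""
        n = self.epochs_per_day
        if (i + 1) * n > len(self):
            raise ValueError(f"day {i} is incomplete")
        return self.slice(i * n, (i + 1) * n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_min": self.t,
            "bgl_mgdl": self.bgl,
            "insulin_U": self.insulin,
            "cho_g": self.cho,
            "valid": self.mask.astype(int),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GlucoseSeries":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {', '.join(missing)}")
        return cls(df["t_min"].to_numpy(float),
                   df["bgl_mgdl"].to_numpy(float),
                   df["insulin_U"].to_numpy(float),
                   df["cho_g"].to_numpy(float),
                   df["valid"].to_numpy().astype(bool))


def empty_series(days: int, dt_min: float = DEFAULT_DT_MIN) -> GlucoseSeries:
    """All-invalid series spanning ``days`` days (used as a meal scaffold)."""
    n = int(round(days * 24 * 60 / dt_min))
    t = np.arange(n) * dt_min
    nan = np.full(n, np.nan)
    return GlucoseSeries(t, nan, np.zeros(n), np.zeros(n),
                         np.zeros(n, dtype=bool))


def write_series(series: GlucoseSeries, path) -> None:
    """Write a series as CSV with the canonical header."""
    series.to_frame().to_csv(path, index=False, float_format="%.10g")


def read_series(path) -> GlucoseSeries:
    """Read a series written by :func:`write_series`.

    Raises
    ------
    ValueError
        If the header misses a column or a row fails to parse; the message
        names the offending column or line.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed series file {path}: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    for col in CSV_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValueError(f"{path}: cannot parse column {col!r} "
                             f"at line {line}")
        df[col] = coerced
    return GlucoseSeries.from_frame(df)
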