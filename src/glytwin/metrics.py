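"""Glycemic outcome metrics: time in range, hypo/hyper exposure, insulin use.

Samples are classified against a closed target band (boundary values count
as in range); exposure is reported both as sample percentages and as counts
of maximal runs of consecutive out-of-band samples ("episodes"), since
event tallies in the clinical literature are sometimes per sample and
sometimes per contiguous excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import GlucoseSeries


@dataclass(frozen=True)
class OutcomeMetrics:
    tir_pct: float
    hypo_pct: float
    hyper_pct: float
    hypo_samples: int
    hyper_samples: int
    hypo_episodes: int
    hyper_episodes: int
    total_insulin: float
    infusion_epochs_per_day: float


def _episodes(flags: np.ndarray) -> int:
    """Number of maximal runs of True."""
    if not flags.any():
        return 0
    padded = np.concatenate([[False], flags])
    return int(np.sum(padded[1:] & ~padded[:-1]))


def outcome_metrics(series: GlucoseSeries,
                    band: tuple[float, float]) -> OutcomeMetrics:
    """Sample-wise classification of a series against a glycemic band."""
    g_min, g_max = band
    if not series.mask.any():
        raise ValueError("series has no valid samples")
    g = series.bgl[series.mask]
    hypo = g < g_min
    hyper = g > g_max
    n = len(g)
    n_days = max(series.n_days, 1)
    infusing = series.insulin > 0
    return OutcomeMetrics(
        tir_pct=100.0 * float(np.sum(~hypo & ~hyper)) / n,
        hypo_pct=100.0 * float(hypo.sum()) / n,
        hyper_pct=100.0 * float(hyper.sum()) / n,
        hypo_samples=int(hypo.sum()),
        hyper_samples=int(hyper.sum()),
        hypo_episodes=_episodes(hypo),
        hyper_episodes=_episodes(hyper),
        total_insulin=float(series.insulin.sum()),
        infusion_epochs_per_day=float(infusing.sum()) / n_days,
    )


@dataclass(frozen=True)
class InsulinSummary:
    baseline_total: float
    controlled_total: float
    reduction_pct: float
    baseline_epochs_per_day: float
    controlled_epochs_per_day: float


def insulin_summary(baseline: GlucoseSeries,
                    controlled: GlucoseSeries) -> InsulinSummary:
    """Total delivered insulin per arm and the percent reduction.

    ``reduction_pct`` is positive when the controlled arm used less insulin;
    the sign is preserved when it used more.
    """
    if len(baseline) == 0 or len(controlled) == 0:
        raise ValueError("both series must be non-empty")
    total_b = float(baseline.insulin.sum())
    total_c = float(controlled.insulin.sum())
    if total_b == 0:
        raise ValueError("baseline delivered no insulin; "
                         "reduction undefined")
    return InsulinSummary(
        baseline_total=total_b,
        controlled_total=total_c,
        reduction_pct=100.0 * (total_b - total_c) / total_b,
        baseline_epochs_per_day=(float((baseline.insulin > 0).sum())
                                 / max(baseline.n_days, 1)),
        controlled_epochs_per_day=(float((controlled.insulin > 0).sum())
                                   / max(controlled.n_days, 1)),
    )


def cohort_report(rows) -> pd.DataFrame:
    """Tabulate per-patient outcomes under both arms plus cohort summary.

    ``rows`` is an iterable of ``(profile, baseline: OutcomeMetrics,
    controlled: OutcomeMetrics)``.  The result has one row per patient with
    TIR / hypo / hyper columns for each arm, percent-improvement columns,
    and min/max/median summary rows appended.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("need at least one patient")
    records = []
    for profile, base, ctrl in rows:
        records.append({
            "id": profile.id,
            "tir_ctrl_pct": ctrl.tir_pct,
            "hypo_ctrl_pct": ctrl.hypo_pct,
            "hyper_ctrl_pct": ctrl.hyper_pct,
            "tir_base_pct": base.tir_pct,
            "hypo_base_pct": base.hypo_pct,
            "hyper_base_pct": base.hyper_pct,
            "tir_improvement_pct": ctrl.tir_pct - base.tir_pct,
            "hypo_improvement_pct": base.hypo_pct - ctrl.hypo_pct,
            "hyper_improvement_pct": base.hyper_pct - ctrl.hyper_pct,
        })
    df = pd.DataFrame.from_records(records)
    numeric = df.drop(columns="id")
    summary = pd.DataFrame({
        "id": ["min", "max", "median"],
        **{c: [numeric[c].min(), numeric[c].max(), numeric[c].median()]
           for c in numeric.columns},
    })
    return pd.concat([df, summary], ignore_index=True)
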