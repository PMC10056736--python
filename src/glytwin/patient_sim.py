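"""Synthetic elderly-T2D virtual patients, meal scenarios and glucose plant.

This module generates the study conditions for every experiment in the
package: a cohort of virtual patients with clinically plausible contextual
profiles (target glycemic band, daily carbohydrate budget, lifestyle), a
meal/therapy scenario generator emulating a 14-day in-clinic protocol with
15-minute CGM sampling, and the ground-truth glucose plant used both as a
fixture generator and as the closed-loop simulation target.

The plant follows a first-order personal glucose model

    G(k+1) = z1*·G(k) + z2*·I(k) + z3*·CHO_abs(k) + (1 − z1*)·Gb + noise

where ``z1*`` is the glucose persistence (dimensionless), ``z2* ≤ 0`` the
insulin sensitivity (mg/dL per unit), ``z3* ≥ 0`` the carbohydrate gain
(mg/dL per gram) and ``Gb`` the drug-free basal glucose.  The basal term
makes the equilibrium without inputs equal to ``Gb`` rather than zero; the
estimator side fits the pure three-parameter recursion and absorbs the
offset into its disturbance term.  Meals pass through a first-order
absorption filter (time constant ``cho_absorption_tau`` epochs) before
entering the dynamics, emulating digestion lag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .series import GlucoseSeries, empty_series, EPOCHS_PER_DAY

#: target-band choices observed in the trial cohort (mg/dL)
BAND_CHOICES: tuple[tuple[float, float], ...] = (
    (70.0, 180.0), (80.0, 140.0), (80.0, 150.0), (80.0, 180.0), (90.0, 180.0),
)

#: nominal meal times, minutes after midnight: breakfast, lunch, snack, dinner
MEAL_TIMES_MIN = (7 * 60 + 30, 13 * 60 + 30, 16 * 60, 20 * 60)

#: uniform jitter applied to each meal time (minutes)
MEAL_JITTER_MIN = 30.0

#: hard pump limit used when screening cohort controllability (U per epoch)
PUMP_MAX_U_PER_EPOCH = 2.5

#: glucose floor preventing nonphysical values (mg/dL)
GLUCOSE_FLOOR = 20.0


@dataclass(frozen=True)
class PatientProfile:
    """Contextual data for one virtual patient."""

    id: str
    age: float
    sex: str
    bmi: float
    comorbidity_tags: frozenset = frozenset()
    target_band: tuple[float, float] = (70.0, 180.0)
    avg_cho_per_day: float = 250.0
    lifestyle: str = "moderate"
    meal_count: int = 4

    def __post_init__(self) -> None:
        g_min, g_max = self.target_band
        if not (g_min < g_max):
            raise ValueError("target band must satisfy g_min < g_max")
        if not (60 <= g_min <= 300 and 60 <= g_max <= 300):
            raise ValueError("target band must lie in [60, 300] mg/dL")
        if self.avg_cho_per_day < 0:
            raise ValueError("avg_cho_per_day must be non-negative")
        if self.meal_count < 1:
            raise ValueError("meal_count must be at least 1")
        if self.lifestyle not in ("active", "moderate", "sedentary"):
            raise ValueError(f"unknown lifestyle {self.lifestyle!r}")


@dataclass(frozen=True)
class VirtualPatientParams:
    """Ground-truth plant parameters for one virtual patient."""

    true_w: tuple[float, float, float]
    basal_glucose: float
    process_noise_sd: float = 2.0
    measurement_noise_sd: float = 4.0
    cho_absorption_tau: float = 2.0
    nonlinearity_mode: str = "linear"
    insulin_sat_units: float = 3.0

    def __post_init__(self) -> None:
        z1, z2, z3 = self.true_w
        if not (0 < z1 < 1):
            raise ValueError("z1* must lie in (0, 1)")
        if z2 > 0:
            raise ValueError("z2* (insulin sensitivity) must be <= 0")
        if z3 < 0:
            raise ValueError("z3* (CHO gain) must be >= 0")
        if self.process_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.basal_glucose <= 0:
            raise ValueError("basal_glucose must be positive")
        if self.nonlinearity_mode not in ("linear", "saturating"):
            raise ValueError(f"unknown mode {self.nonlinearity_mode!r}")


@dataclass(frozen=True)
class TherapySchedule:
    """Pre-programmed pump settings for the open-loop baseline arm."""

    basal_per_epoch: float
    carb_ratio: float  # units per gram, delivered at meal epochs
    bolus_times: tuple[int, ...] | None = None  # None = bolus wherever cho > 0

    def __post_init__(self) -> None:
        if self.basal_per_epoch < 0 or self.carb_ratio < 0:
            raise ValueError("therapy doses must be non-negative")


def sample_cohort(n: int, seed: int,
                  low_cho_outlier_prob: float = 0.05,
                  ) -> list[tuple[PatientProfile, VirtualPatientParams]]:
    """Sample ``n`` virtual patients with profiles and plant parameters.

    Target bands are drawn from the five bands observed in the trial cohort,
    daily carbohydrate budgets from 200–320 g (with a small probability of a
    20 g low-CHO outlier, as seen clinically in renal patients), and the
    glucose-dynamics parameters from the documented ranges z1* in
    [0.85, 0.97], z2* in [-2.5, -0.5] mg/dL/U, z3* in [0.05, 0.3] mg/dL/g.

    A plausibility screen redraws (z2*, basal glucose) until the steady-state
    insulin rate needed to hold the band midpoint stays below 80% of the
    2.5 U/epoch pump limit, so every sampled patient is controllable — the
    analogue of a clinic recruiting patients its pumps can actually treat.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        band = BAND_CHOICES[rng.integers(len(BAND_CHOICES))]
        if rng.random() < low_cho_outlier_prob:
            cho_day = 20.0
        else:
            cho_day = float(rng.uniform(200.0, 320.0))
        profile = PatientProfile(
            id=f"P{i + 1}",
            age=float(rng.uniform(55, 82)),
            sex=str(rng.choice(["F", "M"])),
            bmi=float(rng.uniform(21, 35)),
            comorbidity_tags=frozenset(
                rng.choice(["dyslipidemia", "hypertension", "hypothyroidism",
                            "ckd", "heart_disease"],
                           size=rng.integers(1, 4), replace=False).tolist()),
            target_band=band,
            avg_cho_per_day=cho_day,
            lifestyle=str(rng.choice(["active", "moderate", "sedentary"],
                                     p=[0.33, 0.27, 0.40])),
            meal_count=int(rng.choice([3, 4], p=[0.2, 0.8])),
        )
        g_mid = 0.5 * (band[0] + band[1])
        z1 = float(rng.uniform(0.85, 0.97))
        z3 = float(rng.uniform(0.05, 0.30))
        cho_rate = cho_day / EPOCHS_PER_DAY
        for _ in range(500):
            z2 = float(rng.uniform(-2.5, -0.5))
            gb = float(rng.uniform(g_mid + 15.0, g_mid + 70.0))
            i_ss = ((gb - g_mid) * (1 - z1) + z3 * cho_rate) / abs(z2)
            if i_ss <= 0.8 * PUMP_MAX_U_PER_EPOCH:
                break
        params = VirtualPatientParams(true_w=(z1, z2, z3), basal_glucose=gb)
        cohort.append((profile, params))
    return cohort


def _meal_fractions(meal_count: int) -> np.ndarray:
    # breakfast/lunch/snack/dinner shares of the daily budget; snack <= 15%
    if meal_count >= 4:
        return np.array([0.30, 0.35, 0.10, 0.25])
    return np.array([0.32, 0.38, 0.30])


def generate_meals(profile: PatientProfile, days: int, seed: int,
                   ) -> GlucoseSeries:
    """Jittered daily meal schedule honouring the patient's CHO budget.

    Meals fall at 07:30, 13:30, 16:00 (snack) and 20:00, each jittered
    uniformly within ±30 min and snapped to the 15-min grid; per-day amounts
    are mildly varied but renormalized so each day's total equals
    ``avg_cho_per_day`` exactly.  The insulin channel is zero and the glucose
    channel is left invalid.
    """
    if days < 1:
        raise ValueError("days must be at least 1")
    rng = np.random.default_rng(seed)
    series = empty_series(days)
    dt = series.dt_min
    n_day = series.epochs_per_day
    k_meals = min(profile.meal_count, len(MEAL_TIMES_MIN))
    times = MEAL_TIMES_MIN[:2] + MEAL_TIMES_MIN[2:][:max(0, k_meals - 2)]
    base = _meal_fractions(k_meals)
    for d in range(days):
        frac = base * (1.0 + 0.10 * rng.uniform(-1, 1, size=len(base)))
        frac = frac / frac.sum()
        grams = frac * profile.avg_cho_per_day
        for m, t_nominal in enumerate(times):
            jit = rng.uniform(-MEAL_JITTER_MIN, MEAL_JITTER_MIN)
            epoch = int(round((t_nominal + jit) / dt))
            epoch = min(max(epoch, 0), n_day - 1)
            series.cho[d * n_day + epoch] += grams[m]
    return series


def absorb_meals(cho: np.ndarray, tau: float) -> np.ndarray:
    """First-order gut absorption of meal impulses.

    Each epoch's intake joins an on-board carbohydrate pool; a fraction
    ``1 − exp(−1/tau)`` of the pool is absorbed per epoch.  ``tau = 0``
    means passthrough (absorbed == ingested), used by oracle tests.
    Total absorbed mass converges to total ingested mass.
    """
    cho = np.asarray(cho, dtype=float)
    if tau <= 0:
        return cho.copy()
    a = 1.0 - math.exp(-1.0 / tau)
    out = np.empty_like(cho)
    pool = 0.0
    for k in range(len(cho)):
        pool += cho[k]
        out[k] = a * pool
        pool -= out[k]
    return out


def step_truth(params: VirtualPatientParams, g: float, insulin: float,
               cho_absorbed: float, noise_draw: float = 0.0) -> float:
    """One ground-truth plant step (15-min epoch).

    ``cho_absorbed`` is the carbohydrate mass entering the dynamics this
    epoch (after any absorption filtering).  In saturating mode the insulin
    effect passes through a bounded tanh curve, capping the per-epoch
    glucose drop a large bolus can cause.  Output is floored at 20 mg/dL.
    """
    if g <= 0:
        raise ValueError("glucose must be positive")
    z1, z2, z3 = params.true_w
    if params.nonlinearity_mode == "saturating":
        cap = params.insulin_sat_units
        insulin_eff = cap * math.tanh(insulin / cap) if cap > 0 else insulin
    else:
        insulin_eff = insulin
    g_next = (z1 * g + z2 * insulin_eff + z3 * cho_absorbed
              + (1.0 - z1) * params.basal_glucose + noise_draw)
    return max(g_next, GLUCOSE_FLOOR)


class VirtualPatient:
    """Stateful plant for epoch-by-epoch closed-loop simulation.

    Wraps :func:`step_truth` with the carbohydrate absorption pool and two
    independent seeded noise streams (process and measurement), so a
    closed-loop run is bit-reproducible under a fixed seed.
    """

    def __init__(self, params: VirtualPatientParams, seed: int,
                 g0: float | None = None):
        self.params = params
        ss = np.random.SeedSequence(seed)
        proc_ss, meas_ss = ss.spawn(2)
        self._proc_rng = np.random.default_rng(proc_ss)
        self._meas_rng = np.random.default_rng(meas_ss)
        self.g_true = params.basal_glucose if g0 is None else float(g0)
        self._pool = 0.0
        self._a = (1.0 - math.exp(-1.0 / params.cho_absorption_tau)
                   if params.cho_absorption_tau > 0 else 1.0)

    def measure(self) -> float:
        """CGM reading of the current true glucose (noisy, floored)."""
        noise = self._meas_rng.normal(0.0, self.params.measurement_noise_sd)
        return max(self.g_true + noise, GLUCOSE_FLOOR)

    def step(self, insulin: float, meal_cho: float) -> float:
        """Advance one epoch under the given inputs; returns true glucose."""
        self._pool += meal_cho
        absorbed = self._a * self._pool
        self._pool -= absorbed
        noise = self._proc_rng.normal(0.0, self.params.process_noise_sd)
        self.g_true = step_truth(self.params, self.g_true, insulin,
                                 absorbed, noise)
        return self.g_true


def default_therapy(profile: PatientProfile, params: VirtualPatientParams,
                    basal_factor: float = 1.4,
                    bolus_factor: float = 0.3) -> TherapySchedule:
    """Pre-programmed pump settings emulating diabetologist recommendations.

    Conventional elderly-T2D regimens are basal-heavy: the fixed rate is
    sized to the patient's *average total* requirement — fasting need plus
    the daily carbohydrate load smeared uniformly over the day — inflated
    by ``basal_factor`` as a conservative buffer, while meal boluses cover
    only ``bolus_factor`` of the announced carbohydrates.  Insulin
    therefore flows every epoch of the day.  The timing mismatch of flat
    delivery against peaky need produces the familiar open-loop signature:
    post-prandial hyperglycemia and nocturnal lows despite a *larger*
    total daily dose than adaptive control ends up needing.
    """
    z1, z2, z3 = params.true_w
    g_mid = 0.5 * sum(profile.target_band)
    fasting = max(0.0, (params.basal_glucose - g_mid) * (1 - z1))
    meal_avg = z3 * profile.avg_cho_per_day / EPOCHS_PER_DAY
    return TherapySchedule(
        basal_per_epoch=basal_factor * (fasting + meal_avg) / abs(z2),
        carb_ratio=bolus_factor * z3 / abs(z2),
    )


def simulate_open_loop(params: VirtualPatientParams, profile: PatientProfile,
                       therapy: TherapySchedule, days: int, seed: int,
                       ) -> GlucoseSeries:
    """Open-loop trajectory under fixed pump therapy.

    Basal insulin is delivered every epoch; carb-ratio boluses at meal
    epochs (or, if ``therapy.bolus_times`` is given, only at those epochs).
    The reported glucose channel carries measurement noise; the underlying
    dynamics carry process noise.  Fully seeded.
    """
    if days < 1:
        raise ValueError("days must be at least 1")
    meal_seed, plant_seed = [
        s.generate_state(1)[0] % (2 ** 31)
        for s in np.random.SeedSequence(seed).spawn(2)]
    meals = generate_meals(profile, days, int(meal_seed))
    n = len(meals)
    insulin = np.full(n, therapy.basal_per_epoch)
    if therapy.bolus_times is None:
        bolus_idx = np.flatnonzero(meals.cho > 0)
    else:
        bolus_idx = np.asarray(therapy.bolus_times, dtype=int)
    insulin[bolus_idx] += therapy.carb_ratio * meals.cho[bolus_idx]

    patient = VirtualPatient(params, int(plant_seed))
    bgl = np.empty(n)
    for k in range(n):
        bgl[k] = patient.measure()
        patient.step(insulin[k], meals.cho[k])
    return GlucoseSeries(meals.t, bgl, insulin, meals.cho,
                         np.ones(n, dtype=bool))
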