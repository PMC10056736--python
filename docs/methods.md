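# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the simulations do and do not demonstrate.

## Glucose plant and virtual cohort

The ground-truth patient is a first-order linear (optionally saturating)
glucose model at 15-minute epochs:

    G(k+1) = ζ₁* G(k) + ζ₂* I(k) + ζ₃* CHO_abs(k) + (1 − ζ₁*) G_b + w(k)

* ζ₁* ∈ [0.85, 0.97] — glucose persistence; ζ₂* ∈ [−2.5, −0.5] mg/dL/U —
  insulin sensitivity; ζ₃* ∈ [0.05, 0.3] mg/dL/g — carbohydrate gain.
  These ranges span open-loop behaviours from mild to severe dysglycemia.
* The basal-equilibrium term (1 − ζ₁*)·G_b makes the drug-free steady
  state the patient's basal glucose G_b rather than zero.  The estimator
  deliberately fits the *pure* three-parameter recursion; the offset is
  absorbed by the controller's one-step residual correction ε₁.
* G_b is drawn 15–70 mg/dL above the patient's band midpoint:
  uncontrolled elderly T2D runs hyperglycemic, which is what therapy must
  correct.  A plausibility screen redraws (ζ₂*, G_b) until the
  steady-state dose required to hold the band midpoint stays below 80% of
  the 2.5 U/epoch pump limit — the analogue of a clinic enrolling
  patients its pumps can actually treat.
* Meals pass a first-order absorption filter (τ = 2 epochs ≈ 30 min of
  digestion lag; τ = 0 gives the exact linear recursion used by oracle
  tests).  Process noise is 2 mg/dL per epoch; CGM measurement noise is
  4 mg/dL, chosen so that one-step prediction errors land in the few-
  percent range typical of 15-min CGM data.  The glucose floor of
  20 mg/dL only prevents nonphysical negatives.
* Target bands come from the five bands used clinically for this
  population ({70–180, 80–140, 80–150, 80–180, 90–180} mg/dL); daily
  carbohydrate budgets are 200–320 g with a rare 20 g very-low-CHO
  outlier.  Meals fall at 07:30, 13:30, 16:00 (snack ≤ 15% of budget) and
  20:00, jittered ±30 min, and each day's total equals the budget
  exactly.

### Baseline (conventional) therapy

The open-loop arm emulates basal-heavy pre-programmed pump therapy: the
fixed basal rate is sized to the patient's *average total* requirement
(fasting need plus the daily carbohydrate load smeared uniformly over the
96 epochs), inflated by a per-patient factor of 1.25–1.55, while meal
boluses cover only 30% of announced carbohydrates.  Insulin therefore
flows at every epoch of the day, and the arm overdelivers in total while
mistiming delivery — the characteristic signature that adaptive control
then corrects with less insulin.

**Limitation.**  In a linear plant, mean glucose is tied to total
insulin, so a baseline that overdelivers cannot simultaneously run
strongly hyperglycemic.  The synthetic baseline is consequently better
controlled (TIR often above 80%) than real conventional-therapy cohorts;
what the simulation demonstrates is the *controlled arm's* absolute
performance and the insulin saving at matched meals and noise, not the
magnitude of the TIR improvement over a failing baseline.

## Recursive model estimation

The online model is exponentially weighted recursive least squares with
forgetting factor λ (default 0.98), scalar observation weight (default
1), and a configurable dead zone (default 0: always update).  With λ = 1
and dead zone 0 the recursion is algebraically identical to regularized
batch least squares with the prior implied by the initial inverse-
correlation matrix — an equivalence tested to 1e−8 on every data prefix.

Inside the closed loop the estimator additionally uses (all standard
robust-adaptive-control guards):

* **dead zone 5 mg/dL** — update only on innovations above the CGM noise
  floor;
* **scale-aware diagonal prior** diag(0.1, 1.0, 0.1) — glucose regressors
  are ~100× larger than insulin regressors, and an isotropic prior
  leaves the insulin coefficient essentially unconstrained;
* **covariance limiting** — the trace of the inverse-correlation matrix
  is capped at its initial value, so forgetting cannot inflate
  uncertainty without bound along unexcited directions;
* **projection** onto the physiological region ζ₁ ∈ [0, 1.2],
  ζ₂ ∈ [−10, 0], ζ₃ ∈ [0, 1].

These matter because closed-loop data are barely exciting: between meals
both glucose and insulin are nearly constant, leaving a collinear
direction along which the estimate would otherwise random-walk (the
insulin coefficient drifts ~G/I ≈ 30× faster than the glucose one).
Relatedly, carb-ratio therapy makes insulin an exact linear function of
carbohydrate intake, so (ζ₂, ζ₃) are not separately identifiable from
such records — the loop is designed to dose correctly anyway, through
the per-epoch residual correction rather than exact parameter recovery.
Offline identification from independently exciting inputs recovers true
parameters to 1e−6.

## LSTM forecaster

A stacked two-hidden-layer LSTM (standard input/forget/output/candidate
gates, linear readout) implemented in numpy with full backpropagation
through time and Adam, which keeps training bit-deterministic under a
fixed seed and the model serializable to JSON.  Inputs are 2-hour
windows (8 samples) of the three channels scaled to [0, 1]; the target
is the next glucose sample; multi-step forecasts are recursive, feeding
each prediction back as the glucose input while insulin and carbohydrate
come from announced schedules.

* Trial-style training uses a chronological 70/30 split, with scaling
  statistics from the training split only, early stopping on held-out
  loss, and an optional excluded time interval.
* The in-loop forecaster (trained on the one warm-up day) instead pins
  scaling to fixed physiological bounds (glucose 40–300 mg/dL, insulin
  0–2.5 U, CHO 0–150 g): the loop later operates at glucose levels the
  warm-up never visited, and data-driven scaling would push those inputs
  outside [0, 1].
* Reported errors: `pct_error` is mean absolute percentage error on the
  mg/dL scale; "normalized" RMSE/MAE are computed on the scaled values.
* Defaults: 32 units/layer, 200 epochs (trial-style) — the harness uses
  a reduced 12-unit, 40-epoch configuration, which reaches ~3–4.5%
  one-step error on 14-day synthetic records and keeps a full cohort run
  to minutes.

## Learning-based MPC

The receding-horizon program is a linear program (linear objective,
affine dynamics, box and soft band constraints) solved with HiGHS at
1e−9 feasibility tolerances; on 2-step instances the solution matches
exhaustive grid enumeration within grid resolution.

* Horizon Np = 4 epochs (1 h), sampling 15 min; insulin bounds
  0–2.5 U/epoch are hard; a single per-step slack γ(k) softens both band
  edges at cost c_γ = 10⁴ per mg/dL against c_T = 1 per unit insulin, so
  the program is always feasible.
* ε₁, the latest one-step residual, is held constant over the horizon
  (the model updates between epochs, not during a solve).  It carries
  the basal offset, any unmodelled meal dynamics, and parameter error.
* δa = η₁·ŷ/Ĝ + η₂·Δŷ/h with η₁ = η₂ = 0.05.  Both slope points are
  forecaster outputs (the one-step estimate of the current sample seeds
  the difference), so a constant forecaster bias cancels instead of
  masquerading as a trend.  A "ratio-minus-one" variant (δa → 0 when
  forecast and model agree) is selectable and never mixed with the
  literal form.  Ĝ over the horizon is propagated with zero insulin and
  announced carbohydrates, keeping the program linear in the dose.
* In steady state the loop settles near G_max/(1 + δa) — with δa ≈ 0.05
  that is a ~5% safety margin below the band ceiling, which is how the
  forecast-driven term buys hypoglycemia safety at the price of slightly
  more insulin.  δc is not separately modelled and defaults to 0.
* Future insulin over the forecaster's rollout horizon is unknown at
  decision time; the last applied dose is held constant as the announced
  insulin channel.

## Closed-loop harness

Per epoch: measure → recursive model update → LSTM rollout → LB-MPC
solve → apply the first dose to the plant.  Day 1 is a warm-up on
baseline therapy (the estimator needs excitation and the forecaster
training data); outcome metrics exclude it in *both* arms so the arms
are compared on identical epochs.  Both arms share one meal schedule and
one plant noise stream per patient; all randomness derives from a single
master seed through independent child streams, making whole experiments
bit-reproducible.

## Diagnostics

* Matrix profile: exact vectorized all-pairs scan (raw and z-normalized;
  self-join exclusion zone ⌈m/2⌉; constant windows z-normalize to the
  zero vector by convention).  At 14-day CGM scale (~1300 samples) the
  exact scan runs in well under a second, so no approximate algorithm is
  needed.  Day-to-day distances are reported both raw and per-sample
  (raw/√m) because the clinically meaningful scale depends on window
  length; ties in motif/discord selection break to the earliest
  position.
* Unobserved-components decomposition: local linear trend + dummy
  seasonal (period 96 = one day) + optional cycle + optional regressors,
  maximum likelihood via Kalman filter/smoother (statsmodels).  The
  irregular component is defined as the smoothed remainder, so the five
  components reconstruct the series exactly.  Unit tests exercise a
  period-24 configuration purely for speed; the statistical structure is
  identical.
* Imputation: mean / previous / next with explicit fallback at leading
  or trailing gaps; diagnostics never mutate their input.

## Outcome metrics

Samples are classified against a *closed* target band (boundary values
count as in range).  Exposure is reported as sample percentages (TIR +
hypo + hyper = 100) and as counts of maximal runs of consecutive
out-of-band samples, since clinical "event" tallies are ambiguous
between the two conventions.  Insulin reduction is
100·(Σ baseline − Σ controlled)/Σ baseline over the shared post-warm-up
window; its sign is preserved when control uses more.

## Study sizes

The standard experiment is 15 patients × 14 days (1344 epochs each,
one warm-up day), matching a two-week monitoring protocol; it completes
in ~2 minutes on one CPU.  Unit tests use 2–4 day, 1–2 patient
configurations of the same code paths.
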