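# glytwin

Closed-loop insulin dosing for elderly type-2 diabetes (E-T2D), simulated
end to end: a virtual-patient glucose plant, an online recursive model of
each patient's glucose dynamics, an LSTM glucose forecaster, a
learning-based model-predictive controller (LB-MPC), CGM diagnostics, and
clinical outcome metrics — wired into a seeded two-arm experiment harness.

The package is aimed at researchers studying adaptive glycemic control:
it lets you generate realistic E-T2D cohorts, run conventional
pre-programmed pump therapy against closed-loop LB-MPC on identical meals
and noise, and score both arms with standard CGM metrics (time in range,
hypo/hyper exposure, insulin totals).

## The model

Each patient's glucose dynamics on a 15-minute grid follow

    G(k+1) = ζ₁ G(k) + ζ₂ I(k) + ζ₃ CHO(k) + ε(k)

with glucose persistence ζ₁ (dimensionless), insulin sensitivity ζ₂ ≤ 0
(mg/dL per unit), carbohydrate gain ζ₃ ≥ 0 (mg/dL per gram).  The
parameter vector w = (ζ₁, ζ₂, ζ₃) is estimated online by recursive least
squares with forgetting factor λ, so slow drifts in insulin response are
tracked.  Each epoch the controller solves the linear program

    min   Σₖ c_T·I(k) + c_γ·γ(k)
    s.t.  G(k+1) = (ζ₁ + δa(k))·G(k) + ζ₂ I(k) + (ζ₃ + δc)·CHO(k) + ε₁
          G_min − γ(k) ≤ G(k) ≤ G_max + γ(k),  I_min ≤ I(k) ≤ I_max,
          γ(k) ≥ 0

over a 4-step (1 h) horizon and applies only the first dose (receding
horizon).  ε₁ is the latest one-step model residual; δa fuses the LSTM
forecast ŷ with the model estimate Ĝ:

    δa = η₁ · ŷ(k+1)/Ĝ(k+1) + η₂ · (ŷ(k+1) − ŷ(k))/h

When forecast and model agree, δa ≈ η₁ > 0: the controller deliberately
over-predicts glucose persistence, which settles the patient a safety
margin below the band ceiling — the learned term encodes conservative
dosing for geriatric patients.  Slack variables γ make the band soft (the
program is always feasible); insulin bounds are hard.

The LSTM forecaster (two hidden layers, implemented in numpy with
backpropagation through time) consumes 2-hour windows of glucose, insulin
and carbohydrate, and rolls forecasts forward recursively, feeding each
prediction back as the next glucose input.  Diagnostics include matrix
profile motif/discord discovery, day-to-day distances, ACF/PACF and an
unobserved-components decomposition (trend + daily seasonal + irregular).

## Worked example

Sample a virtual patient and score conventional therapy:

```python
from glytwin import (sample_cohort, default_therapy, simulate_open_loop,
                     outcome_metrics)

profile, params = sample_cohort(n=1, seed=7)[0]
print(profile.id, profile.target_band, round(profile.avg_cho_per_day))
# P1 (90.0, 180.0) 293

series = simulate_open_loop(params, profile,
                            default_therapy(profile, params),
                            days=14, seed=7)
m = outcome_metrics(series, profile.target_band)
print(f"TIR {m.tir_pct:.1f}%  hypo {m.hypo_pct:.1f}%  "
      f"hyper {m.hyper_pct:.1f}%  insulin {m.total_insulin:.0f} U")
# TIR 100.0%  hypo 0.0%  hyper 0.0%  insulin 2252 U
```

Run the two-arm experiment from the shell (3 patients, 5 days shown;
the full study is 15 patients, 14 days):

```sh
$ glytwin demo --seed 7 --patients 3 --days 5 --out demo_out
    id  tir_ctrl_pct  hypo_ctrl_pct  hyper_ctrl_pct  tir_base_pct ...
    P1         100.0            0.0             0.0          99.7
    P2         100.0            0.0             0.0         100.0
    P3         100.0            0.0             0.0         100.0
   ...
cohort min TIR: 100.0%
cohort max time-in-hypo: 0.0%
cohort max time-in-hyper: 0.0%
cohort min insulin reduction: 32.8%
```

Per patient, `tir_ctrl_pct` is the percentage of post-warm-up CGM samples
inside the patient's own target band under closed-loop control,
`tir_base_pct` the same under pre-programmed therapy, and the cohort
"insulin reduction" is how much less total insulin the closed loop
delivered than the baseline arm on identical meals — here every patient
stays fully in range while using at least a third less insulin.

Other CLI verbs: `glytwin simulate` (open-loop cohort), `glytwin control
--config exp.yaml` (closed loop from a config file), `glytwin diagnose
--series s.csv --m 96` (matrix profile + structural decomposition), and
`glytwin report --series s.csv --band 80 140`.

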