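# comfeedback

Delayed center-of-mass (CoM) feedback decomposition of perturbation-evoked
balance muscle activity.

When a standing person's support surface translates, the tibialis anterior
and medial gastrocnemius respond with bursts of activity at reflex-like
latencies. This package models those EMG envelopes as delayed, gain-weighted,
half-wave-rectified feedback on task-level balance error — CoM displacement
`d`, velocity `v` and acceleration `a` relative to the base of support — and
decomposes each muscle's response into hierarchical components:

* **agonist** (the muscle stretched by the perturbation): a brainstem-latency
  loop (LLR1, ~119 ms) plus a cortical-latency loop (LLR2, ~200 ms),
* **antagonist** (the muscle shortened by the perturbation): a *stabilizing*
  loop driven by kinematics that stretch it (at the platform's deceleration)
  plus a *destabilizing* loop driven by kinematics that shorten it, the
  latter further split into its acceleration and velocity+displacement parts.

Each loop is

```
emg_i(t) = ⌊ σ_i ( k_d,i · d(t−λ_i) + k_v,i · v(t−λ_i) + k_a,i · a(t−λ_i) ) ⌋
```

with `⌊·⌋ = max(0, ·)`, `σ_i = ±1` for stretch/shorten predictors, and the
muscle reconstruction is `emg(t) = emg_1(t) + emg_2(t)`. Parameters are
identified per participant × direction × magnitude by minimizing

```
J = μ_s ∫ e² dt + μ_m max|e| + μ_k kᵀk ,   μ_s:μ_m:μ_k = 1 : 1 : 10⁻⁶
```

over a two-stage constrained search: single-loop fits (delay-grid seeding
with non-negative least-squares gain starts, plus alternating residual
backfits) seed a joint bounded refinement (gains ±10 %, delays ±10 ms of the
seeds). Goodness of fit is reported as regression R² and VAF (100 × squared
uncentered correlation); components are quantified as trapezoidal integrals.

Because the human cohort this kind of study records is not publicly
deposited, the package ships a synthetic generator that emulates the
protocol — ramp-and-hold translations at three magnitudes × two directions,
eight trials per condition (48/participant), CoM responses from a damped
second-order stance model, and EMG produced by the package's own forward
model with known ground truth — so every stage is verifiable by parameter
recovery. It is intended for researchers in posture and sensorimotor control
who want a tested, reusable reference implementation of this model family.

## Worked example

`python examples/03_fit_one_condition.py` generates a noise-free agonist
envelope from known loop parameters and fits it back:

```
fit quality: R^2 = 0.9997, VAF = 99.98%, cost = 4.67e-03
LLR1: delay true 119.0 ms -> fitted 119.7 ms
      gains true (k_d, k_v, k_a) = [1.0, 0.8, 0.3]
      gains fitted               = [0.015, 0.735, 0.305]
LLR2: delay true 200.0 ms -> fitted 199.9 ms
      gains true (k_d, k_v, k_a) = [6.0, 0.5, 0.15]
      gains fitted               = [5.822, 0.523, 0.148]
```

Both loop delays are recovered to within a millisecond and the dominant
gains to a few percent; the LLR1 displacement gain contributes at most
~0.01 normalized units to the trace and is the least constrained parameter.
The other examples build the platform/CoM simulation (`01`), the forward
reconstruction and destabilizing split (`02`), and a full cohort pipeline
run with summary tables (`04`).

A thin CLI wraps the same library calls:

```
comfb synth --n-oa 2 --n-pd 2 --seed 1 --out cohort/
comfb run-all --n-oa 2 --n-pd 2 --seed 1 --out demo/
```

## Layout

```
src/comfeedback/
  series.py         uniformly sampled signals, aligned CoM kinematics
  model.py          delayed-feedback loops, dual-loop reconstruction
  synthetic.py      perturbation profiles, stance dynamics, cohort generator
  preprocessing.py  EMG envelope chain, epoching, normalization, averaging
  fitting.py        penalized cost, two-stage constrained identification
  metrics.py        R², VAF, component integrals, latency tables
  pipeline.py       cohort orchestration and summary tables
  cli.py            `comfb` command-line shell
docs/methods.md     model, conventions and numerical choices in detail
examples/           one narrative script per capability
```
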