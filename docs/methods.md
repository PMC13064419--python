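# Methods

## The model

Perturbation-evoked muscle activity is reconstructed from task-level balance
error: CoM displacement `d`, velocity `v` and acceleration `a` relative to
the base of support, expressed per trial in the frame in which positive
values stretch the analyzed muscle (forward translations are analyzed
against TA, backward against MG; the flip is metadata-driven). One feedback
loop is

    s(t) = max(0, σ (k_d d(t−λ) + k_v v(t−λ) + k_a a(t−λ))),

a common delay λ applied to all three predictors, non-negative gains, and
half-wave rectification representing net drive to motor pools. σ = +1 for
predictors that stretch the muscle, −1 for predictors that shorten it. A
muscle is the linear sum of two loops:

* agonist = LLR1 (stretch, short latency) + LLR2 (stretch, longer latency),
  with λ₁ < λ₂ enforced;
* antagonist = stabilizing (stretch) + destabilizing (shorten); the
  destabilizing loop is additionally split into a CoM-acceleration component
  `max(0, −k_a a(t−λ))` and a velocity+displacement component
  `max(0, −k_v v(t−λ) − k_d d(t−λ))`. Each part is rectified individually,
  so the parts need not sum to the jointly rectified loop; the residual is
  an interaction term and both parts are reported with their integrals.

Assumptions worth making explicit: feedback is open-loop from measured
kinematics (no closed-loop body simulation from EMG), activation dynamics
are absorbed into the loop delay, and gains are constant within a condition
average.

### Delayed lookups

Delays are continuous optimization variables, so fractional-sample lookups
use linear interpolation of the kinematic channels; sample rounding would
stair-step the cost surface. Delayed samples are read from real pre-onset
data in the epoch head whenever possible. A lookup may reach at most 0.1 s
before the first sample, in which case the earliest sample is held: quiet
stance precedes the epoch, so the held value is the rest state. This
bounded hold is needed because the LLR2 delay range (up to 0.28 s) exceeds
the 0.2 s epoch head at the fit-window start; shortfalls beyond 0.1 s raise
an error rather than fabricating signal.

## Parameter identification

The cost over the fit window `[t_start, t_end]` is

    J = μ_s ∫ e² dt + μ_m max|e| + μ_k kᵀk,

with `e = recorded − reconstructed`, trapezoidal quadrature, the max taken
over the same window, `k` the gain vector of the model being fit, and
weights in ratio 1 : 1 : 10⁻⁶. The default window is [0, 0.8] s: it covers
both agonist bursts and the deceleration-locked stabilizing burst
(deceleration at 0.5 s plus ~0.135 s latency) while excluding late voluntary
activity. R² and VAF are evaluated on the same window (a flag widens them to
the whole epoch).

Identification is staged:

1. **Stage 1 — per-loop seeding.** For each loop role the delay is scanned
   on a 5 ms grid over a physiological range (LLR1 0.07–0.18 s, LLR2
   0.15–0.28 s, stabilizing 0.08–0.20 s, destabilizing 0.12–0.25 s). At each
   grid delay the gains start from non-negative least squares on the
   un-rectified delayed design; for a non-negative target the rows where the
   envelope is zero are excluded from the least-squares subproblem (there
   the rectifier, not the linear model, explains the data). Local minima of
   the grid cost — not just the global grid-best — are refined in
   (gains, delay) within ±5 ms; ties break toward the smaller delay.
2. **Residual backfitting.** A single loop fit to a two-burst envelope
   over-claims activity the other loop explains better, and under the
   max-error-dominated cost its delay drifts toward the larger burst — on
   superposed envelopes the single-loop cost can be monotone in delay with
   no basin at the second loop's true latency. Seed *pairs* are therefore
   also built by coordinate descent: fit loop A, refit loop B on the
   residual, alternate (up to 10 rounds, keeping the best pair).
3. **Stage 2 — bounded joint refinement.** From every candidate pair, all
   eight parameters are refit jointly with gains bounded to ±10 % and delays
   to ±10 ms of their seeds; the lowest final cost wins. Up to two
   re-centered polishing rounds re-anchor the same box on the current
   optimum and stop when the cost stops improving. Every bounded solve
   returns its seed if it cannot improve on it, so the final cost never
   exceeds the initialization cost.

The cost is non-smooth in the delay (rectification and the max-error term),
so the local optimizer is bounded derivative-free Powell with parameter
tolerance 1e−9, objective tolerance 1e−7 and at most 1e5 evaluations per
solve. Identical inputs give identical results; nothing in the fit is
randomized.

## Preprocessing conventions

* **Raw EMG → envelope** (for `emg_kind: raw` data): zero-phase sixth-order
  Butterworth high-pass at 35 Hz, whole-trial mean subtraction, half-wave
  rectification at 0, zero-phase low-pass at 40 Hz. "Zero-phase" is
  forward–backward filtering with even-reflection padding of 3× the filter
  order; 6 is read as the design order of each pass. The low-pass order is
  not standardized in this model family and defaults to 6 (configurable).
  The final trace is clipped at 0 — the low-pass can undershoot slightly —
  so envelopes are non-negative by contract.
* **Epoch**: half-open [−0.2, 1.2) s around perturbation onset, 1400 samples
  at 1000 Hz, onset at t = 0.
* **Normalization**: one shared factor per participant (and muscle) scaling
  the global maximum across all trials to 1.
* **Averaging/exclusion**: stepping trials are dropped (they change the task
  goal); a condition with fewer than 3 non-stepping trials is excluded and
  reported, not fit.
* **CoM velocity**: third-order Savitzky–Golay smoothing with a 49-sample
  window (the nearest odd width to the nominal 48; symmetric SG windows must
  be odd) followed by central differences. At 100 Hz the window spans
  0.48 s and attenuates a 1 Hz component by ~2 % — a real property of the
  stated filter, reflected in the test tolerances.
* **CoM acceleration**: ground-reaction force divided by body mass.
* **Alignment**: 100 Hz kinematics are linearly interpolated onto the
  1000 Hz EMG grid; extrapolation is refused.
* **Background activity**: tonic pre-onset EMG is *not* subtracted by
  default. The flag exists (`subtract_baseline`) and the recovery fixtures
  enable it, because the feedback model cannot express a tonic offset and
  leaving it in measurably biases delays (~3 ms) and gains (tens of
  percent) even on noise-free data.

## The synthetic generator

The generator defines the study conditions every test runs under.

* **Platform**: raised-cosine acceleration pulse pairs satisfying the
  protocol's peak acceleration and peak velocity exactly (pulse width
  2·V/A), 0.5 s between acceleration and deceleration onset; displacement is
  emergent (≈ V/2 per 0.5 s plateau), since the printed d/v/a triples are
  not jointly consistent with any bang-bang profile and real actuators are
  smooth. Magnitudes: small 5.1 cm / 11.1 cm/s / 0.15 g; medium and large
  use midpoints of the height-adjusted protocol ranges (0.072 m, 0.1565 m/s,
  0.215 g; 0.0935 m, 0.2005 m/s, 0.275 g). Backward trials are exact
  negations.
* **Stance dynamics**: CoM-relative displacement follows
  d̈ + 2ζωḋ + ω²d = −g_c·a_platform with ω = 3 rad/s, ζ = 1.2, g_c = 1,
  integrated as a linear state-space system; acceleration is evaluated from
  the state equation so v = ḋ and a = v̇ hold exactly on the grid. The
  defaults put the CoM excursion peak ~390 ms post-onset, giving d, v, a
  distinct time courses. This is an identifiability device, not a
  biomechanical claim.
* **Ground truth**: delay means follow the latencies typical of these
  responses (LLR1 119 ms, LLR2 200 ms, destabilizing 181 ms, stabilizing
  135 ms relative to the kinematic reversal at deceleration). Gains are
  chosen so the two loops of each muscle differ in dominant predictor —
  LLR1 and destabilizing acceleration-dominant, LLR2
  displacement-dominant — and so envelopes peak near 0.3–0.5 normalized
  units under the small perturbation. Per-participant draws: lognormal gains
  (CV 0.2), normal delays (SD 8 ms) clipped to the grid interiors, with at
  least 30 ms between the agonist delays. The PD group draws a 1.5× larger
  destabilizing acceleration gain on average. Per-magnitude gain multipliers
  (1.0/1.15/1.3) ride on top of the kinematic scaling.
* **EMG**: envelope = baseline (0.05) + forward reconstruction + zero-mean
  Gaussian noise low-pass filtered at 40 Hz and rescaled to `noise_sd`
  (default 0.03), then rectified at 0. These are *envelopes*, not
  carrier-modulated interference EMG; cohort manifests mark
  `emg_kind: envelope` and the pipeline applies epoching/normalization/
  averaging to them, reserving the raw filter chain for `emg_kind: raw`.
* **Trial structure**: 8 trials × 3 magnitudes × 2 directions per
  participant; 2 % multiplicative kinematic jitter per trial; 8.71 % of
  trials flagged as stepping by default. The clinical balance score
  (0–28, higher is better) is 28 − 24·k_aD + N(0, 1.6²), clipped — a
  designed ≈ −0.6 correlation between the score and destabilizing activity.
  All randomness flows from one seed through per-participant and per-trial
  sub-generators.

What passing recovery tests show — and what they do not: the synthetic
envelopes are realizable by the model class, with burst structure matching
the latency priors, smooth unimodal kinematics and stationary noise. Real
EMG contains activity the model cannot represent (voluntary drive, tremor,
electrode artifacts), real bursts are sharper than rectified kinematics, and
real reconstruction accuracies are far below the VAF ≈ 100 seen here.
Recovery results validate the estimator, not the physiology.

## Problem sizes

The test suite and the acceptance script use: 20 noise-free conditions per
muscle (40 two-stage fits) for recovery, 6–12 conditions at envelope SNR 10,
10 single-participant cohorts (8 averaged trials per magnitude) for the
LLR2 magnitude-ordering check, 30 participants for the clinical-score
correlation, and 1-participant, 3-trial cohorts for the end-to-end
determinism check. These sizes give stable medians while keeping a full run
in the minutes range on one CPU; all of them scale up by changing one count.

## Known limitations

* Stage-2 bounds are trust-region-like re-anchored boxes; there is no global
  optimality guarantee, and occasional conditions (a few percent) settle in
  a neighboring basin (visible as VAF ≈ 90 instead of ≈ 100 on noise-free
  data). Medians are the intended summaries.
* Gains whose predictor contributes little to the trace within the active
  window (e.g. the LLR1 displacement gain) are weakly identified; the
  μ_k penalty shrinks them rather than fixing them.
* The inferential layer of a typical study (mixed-effects models, post
  hocs) is intentionally out of scope; the pipeline emits descriptive
  tables and plain Pearson correlations, and the long-format CSVs feed any
  stats package.
* No musculoskeletal or multi-segment simulation, no stepping biomechanics,
  no marker-set CoM computation; stepping flags and (for real data) CoM
  traces are inputs.
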