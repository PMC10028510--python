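# Methods

## The personalization loop

`flowloop` models dynamic difficulty adjustment as a closed loop of six
modules with one-way data flow:

1. **Game and user** (`flowloop.game`) — produces game-native observations:
   an end-of-session score and a 1 Hz heart-rate stream. Either scripted
   (deterministic replay) or simulated from a latent-skill player model.
2. **Feature abstraction** (`flowloop.abstraction`) — wraps each observation
   into a generic `FeatureSample` (feature id, value, session, phase,
   optional tick). The wrap is lossless; no normalization is applied,
   because choosing a scale would itself require game knowledge the
   independent modules must not hold.
3. **Knowledge base** (`flowloop.knowledge`) — per-feature expert rules: the
   heart-rate ceiling function and the score-trend evaluator, each with the
   names of the context parameters it needs.
4. **Interpreter** (`flowloop.personalizer.Interpreter`) — combines sample,
   knowledge and context into a `ProcessedValue`: a signed need on [−1, 1].
   Sign convention, used everywhere: positive = reduce challenge.
5. **Personalization engine** (`flowloop.personalizer`) — a model locator
   routes processed values to the active pluggable model, which emits
   `PersonalizedValue` commands (a dimensionless delta plus timing).
   Several models may be registered at once; a study activates one per mode.
6. **Action abstraction** (`flowloop.abstraction.transform_action`) — maps
   the generic delta one-to-one onto the game's single action, speed
   (≡ difficulty), clamped to its bounds by the game.

The decoupling contract is testable: the personalizer's output is a function
of the `FeatureSample` stream alone, so swapping the game for a stub that
emits the same samples leaves every command unchanged (asserted in the test
suite), and the personalizer module imports nothing game-specific.

## Interpretation rules

**Heart rate.** The ceiling is `hr_max = (220 − age) × intensity`, the
textbook age-predicted maximum scaled by prescribed exercise intensity;
a configured override (180 bpm in all packaged scenarios, standing in for a
clinician-set limit) takes precedence. Sex is part of the declared context
so finer formulas can use it; the default formula does not. Post-session
samples carry the session-mean heart rate: `need = clip((v − hr_max)/hr_max,
−1, 1)`, `over_limit = v > hr_max`, and `rising` is true when the mean
exceeds the previous session's by more than 1 bpm (undefined, hence false,
at the first session). In-session samples are EWMA-smoothed with α = 0.3,
seeded with the first sample of each session — seeding with the first sample
avoids a warm-up bias toward zero, at the cost of trusting one raw sample.

**Score.** The previous scores plus the current one form the series; the
last `min(N, len)` entries (N = 5) get an OLS slope against game index
0..w−1, computed in closed form so a flat series yields exactly zero. The
slope is normalized by the window mean (guarded by ε = 10⁻⁹), making the
trend class invariant to the game's score scale. The dead-band ±0.05 on the
normalized slope absorbs noise: within it the trend is *constant*. A single
available score yields no trend and no adaptation — the first game never
triggers a score command.

## Rule models and their constants

All step constants are design parameters of the rule models, not
physiological facts; each is overridable through `RunConfig`.

| parameter | default | units | role |
|---|---|---|---|
| `constant_step` | +0.01 | difficulty/game | slow rise while the trend is flat |
| `slope_gain` | 0.5 | difficulty per unit norm. slope | proportional trend response |
| `max_step` | 0.08 | difficulty/game | clip on trend-proportional steps |
| `hr_over_step` | 0.05 | difficulty/game | offline decrement when mean HR > ceiling |
| `realtime_step` | 0.02 | difficulty | immediate decrement per exceedance |
| `t_eval` | 5 | s | spacing of real-time evaluation instants |
| `ewma_alpha` | 0.3 | — | heart-rate smoothing weight |
| `rising_threshold` | 1.0 | bpm/session | what counts as a rising heart rate |
| `window` / `dead_band` | 5 / 0.05 | games / — | trend estimator |

The offline score+heart-rate model applies strict precedence
`over_limit > rising > trend`: safety dominates, a rising heart rate holds
the difficulty even when a constant score trend would raise it, and the
score model acts only when the heart rate is quiet. The real-time model
reacts only to heart rate in-session (scores exist only at session end in
this game); at session end it applies the score model only if no immediate
command was issued that session and the heart rate is not rising.

Difficulty bounds d ∈ [0.2, 1.6] with start 0.8; sessions last 60 s at 1 Hz
sampling. Session length, bounds and rates are pinned for reproducibility
and configurable; with t_eval = 5 s each session has 12 evaluation instants
(at seconds 5, 10, …, 60), and a command issued at the final instant counts
toward the difficulty carried into the next session.

## What the scenario generator emulates — and what it does not

The four packaged scenarios are seed-free, bit-deterministic fixtures. The
three score scenarios realize qualitative shapes (diverging-then-constant,
upward after a dip, downward after a plateau) in arbitrary consistent score
units; only shape-level behavior is meaningful. The rising-heart-rate
scenario is constructed so three facts hold exactly: per-game means
`m(g) = 128 + 2g` rise by 2 bpm/game, the within-session ramp spans
`m ± 2`, so the instantaneous rate first exceeds 180 bpm in game 26
(max 182), the session mean first exceeds it in game 27, and that mean is
exactly 182 bpm. On this scenario the loop's timing follows analytically:
offline holds 0.8 while the heart rate rises sub-ceiling, steps −0.05 for
games 28–30 (minimum 0.65 at game 30); real-time issues its first
decrements during game 26 and is below the offline minimum by game 27.

Real rehabilitation data differ in every inconvenient way: noisy,
artifact-laden heart rates; skill drift and fatigue; missing sessions.
Passing these studies shows the loop's plumbing and timing semantics are
correct, not that the rule constants are clinically calibrated. The
latent-player mode adds seeded noise and a challenge–skill score response
(Gaussian in the difficulty–skill mismatch, width 0.3; heart rate relaxing
toward a difficulty-dependent plateau with a 20 s time constant) but is a
toy, not a physiological simulator.

## Numerical and design choices

* OLS slope in closed form (centered cross-products); flat series give
  slope exactly 0 and class *constant*; ties break toward *constant* since
  the dead-band comparison is strict.
* A value exactly at the ceiling is *not* an exceedance (strict `>`),
  matching the scenario design where game 25's maximum and game 26's mean
  both equal 180 exactly.
* End-of-session difficulty — the per-game summary all metrics use — is the
  value carried into the next session.
* Offline commands apply at session boundaries; real-time commands from the
  next tick, never retroactively.
* Scenario and trace CSVs are written with `%.17g` and read with
  round-trip float parsing, so serialization is bit-exact.
* Degenerate inputs: an empty scenario yields an empty trace, no commands
  and no metrics; metric computation on an explicitly empty trace is an
  error; short score histories truncate rather than fail.

## Known limitations

* The score model's steps scale with the mean-normalized slope, so a
  pointwise-greater score series can receive *smaller* steps (its mean is
  larger). Monotonicity holds in the normalized slope, not in raw scores —
  an intended consequence of scale invariance.
* Routing supports one active model per mode; concurrent active models with
  overlapping inputs are rejected as ambiguous rather than arbitrated.
* The knowledge base is a function registry; ontology-backed knowledge
  (OWL/RDF) is out of scope, as are learned personalization models — the
  `ModelSpec` registry is the extension point for both.
* No real sensor ingestion or rendering: the game module is a simulator by
  design.
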