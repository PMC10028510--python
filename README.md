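# flowloop

A decoupled personalization loop for adaptive serious health games, with a
simulated shoulder-rehabilitation game and a study harness comparing offline
versus real-time difficulty adaptation.

## The problem

Serious games for physical rehabilitation work only when the challenge
matches the player's ability: too easy and the patient is bored, too hard
and they are frustrated or — worse — physically strained. Keeping the player
in that band (the *flow channel*) requires dynamic difficulty adjustment
driven by gameplay and physiological signals. Building that adaptation logic
directly into each game entangles clinical knowledge, game code, and
adaptation algorithms; `flowloop` implements the alternative: a loop of
small modules with strict boundaries, so that the adaptation core is
reusable across games and the clinical rules live in one place.

The loop is: **game → feature abstraction → interpreter (with knowledge
base and context locator) → personalization engine → action abstraction →
game**. Game-specific code exists only at the two abstraction boundaries;
the interpreter and the engine never see game units or game constants.

## The model

The packaged proof of concept is a Flappy-Bird-style shoulder-rehab game
whose single action is the game speed (one normalized difficulty scalar
*d* ∈ [0.2, 1.6], starting at *d*₀ = 0.8). Two features drive adaptation:

* **Score trend.** Over the last *N* = 5 game scores the interpreter fits an
  OLS slope *b* against game index and normalizes it by the window mean,
  *b̃* = *b*/ȳ. The trend is *upward* if *b̃* > 0.05, *downward* if
  *b̃* < −0.05, else *constant*. The offline score model steps the
  difficulty by +0.01 per game while the trend is constant, and by
  clip(0.5 *b̃*, ±0.08) while it is upward or downward.
* **Heart-rate safety.** The knowledge base computes the highest accepted
  heart rate, by default (220 − age) × intensity, overridden to 180 bpm in
  all packaged scenarios. The combined offline model applies strict
  precedence: a session-mean heart rate above the ceiling forces −0.05 for
  the next game; a rising (> +1 bpm/session) sub-ceiling heart rate holds
  the difficulty; only otherwise does the score model act. The real-time
  model smooths the 1 Hz heart-rate stream with an EWMA (α = 0.3, seeded
  with the first sample of each session), checks it every 5 s, and applies
  −0.02 immediately at every exceedance of the ceiling.

Four deterministic 30-game scenarios exercise the loop: constant, upward,
and downward score trajectories, and a rising-heart-rate scenario whose
session means increase by exactly 2 bpm per game and cross the 180 bpm
ceiling instantaneously in game 26 and on session average in game 27
(mean 182 bpm).

## Worked example

```sh
flowloop run-study --scenario fig10_rising --mode offline --mode realtime --out out/
```

prints

```
Personalization study: scenario=fig10_rising mode=offline
  games: 30, commands: 29
  first_decrease_game: 28
  argmin_game: 30
  min_difficulty: 0.6499999999999999
Personalization study: scenario=fig10_rising mode=realtime
  games: 30, commands: 54
  first_decrease_game: 26
  argmin_game: 28
  min_difficulty: 0.2
  reach_game: 27
```

Reading this: in offline mode the loop can only react after a completed
session, so the first game played at a lower difficulty is game 28 — one
game after the session-mean heart rate first exceeds the ceiling (game 27,
mean 182 bpm) — and the trace reaches its minimum (0.65) only in the last
game. In real-time mode the loop reacts during game 26, the first session
whose instantaneous heart rate crosses 180 bpm, and is already at or below
the offline run's minimum by game 27 (`reach_game`). The run also writes
per-game trace CSVs, metrics JSON and a hash manifest to `out/`.

The same loop runs closed-loop against a latent-skill player
(`flowloop demo-latent --games 5 --seed 3`), and
`flowloop export-scenario --name fig10_rising --out dir/` writes the
scenario inputs as plain CSV. The Python API mirrors the CLI:
`run_study(gen_hr_scenario("fig10_rising"))` returns per-mode
`StudyResult` objects with traces, command logs, metrics and `summary()`.

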