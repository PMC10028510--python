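"""Game-and-user stand-in: scripted session replay and a latent-skill player.

The proof-of-concept game is Flappy-Bird-like: the player keeps a character
airborne by lifting the outstretched arm to shoulder level; the score is how
long the character survives.  Its single personalizable action is the game
*speed*, treated throughout as one normalized difficulty scalar.

Two modes stand in for real play:

* :func:`play_session_scripted` replays a pre-scripted score and per-tick
  heart-rate trace, optionally letting a real-time hook lower the difficulty
  mid-session (changes take effect from the next tick).
* :func:`play_session_latent` simulates a player with a latent skill level:
  survival time peaks when difficulty matches skill, and heart rate rises
  from rest toward a plateau that grows with difficulty.  Fully reproducible
  for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ActionError, DomainError, ScriptError
from .knowledge import Sex

#: session length in seconds; heart rate is sampled at 1 Hz
SESSION_LENGTH = 60

#: normalized difficulty (speed) bounds and session start value
D_MIN = 0.2
D_MAX = 1.6
D_START = 0.8


@dataclass(frozen=True)
class PlayerProfile:
    """Static player context: demographics and latent ability."""

    age: float = 25.0
    sex: Sex = Sex.MALE
    skill: float = 0.8  # latent, same scale as difficulty
    resting_hr: float = 60.0  # bpm
    intensity: float = 1.0  # prescribed exercise intensity in (0, 1]

    def __post_init__(self) -> None:
        if not 30.0 <= self.resting_hr <= 120.0:
            raise DomainError(f"resting_hr must lie in [30, 120], got {self.resting_hr}")
        if self.skill < 0:
            raise DomainError(f"skill must be >= 0, got {self.skill}")


@dataclass(frozen=True)
class GameState:
    """Current difficulty and position within the exercise session."""

    difficulty: float = D_START
    session_index: int = 1
    tick: int = 0
    d_min: float = D_MIN
    d_max: float = D_MAX

    def __post_init__(self) -> None:
        if not self.d_min <= self.difficulty <= self.d_max:
            raise DomainError(
                f"difficulty {self.difficulty} outside [{self.d_min}, {self.d_max}]"
            )


@dataclass(frozen=True)
class SessionRecord:
    """One completed game session."""

    session_index: int
    score: float
    hr_trace: tuple[float, ...] | None
    difficulty_trace: tuple[float, ...]
    end_difficulty: float


# the hook receives (tick, raw bpm sample, current difficulty) once per tick
# and may return a new target difficulty applied from the next tick onward
RealtimeHook = Callable[[int, float, float], float | None]


def clip_difficulty(value: float, d_min: float = D_MIN, d_max: float = D_MAX) -> float:
    return min(max(value, d_min), d_max)


def play_session_scripted(
    session_index: int,
    difficulty_in: float,
    score_script: float,
    hr_script: Sequence[float] | None = None,
    realtime_hook: RealtimeHook | None = None,
    session_length: int = SESSION_LENGTH,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
) -> SessionRecord:
    """Replay one scripted session.

    Without a hook the difficulty trace is constant at ``difficulty_in``
    (offline adaptation only touches session boundaries).  With a hook, any
    difficulty it requests is clamped and applied from the next tick; the
    record's ``end_difficulty`` is the value carried into the next session,
    so a change requested on the final tick still counts.
    """
    if not d_min <= difficulty_in <= d_max:
        raise DomainError(f"difficulty_in {difficulty_in} outside [{d_min}, {d_max}]")
    if hr_script is not None and len(hr_script) != session_length:
        raise ScriptError(
            f"hr script has {len(hr_script)} samples, session needs {session_length}"
        )
    if realtime_hook is not None and hr_script is None:
        raise ScriptError("a real-time hook needs an hr script to react to")

    difficulty = difficulty_in
    pending: float | None = None
    trace: list[float] = []
    for t in range(session_length):
        if pending is not None:
            difficulty = pending
            pending = None
        trace.append(difficulty)
        if hr_script is not None and realtime_hook is not None:
            requested = realtime_hook(t, float(hr_script[t]), difficulty)
            if requested is not None:
                pending = clip_difficulty(requested, d_min, d_max)

    end_difficulty = pending if pending is not None else difficulty
    return SessionRecord(
        session_index=session_index,
        score=float(score_script),
        hr_trace=tuple(float(v) for v in hr_script) if hr_script is not None else None,
        difficulty_trace=tuple(trace),
        end_difficulty=end_difficulty,
    )


def play_session_latent(
    profile: PlayerProfile,
    difficulty_in: float,
    rng_seed: int,
    session_index: int = 1,
    session_length: int = SESSION_LENGTH,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
    noise_sd: float = 2.0,
    skill_width: float = 0.3,
) -> SessionRecord:
    """Simulate one session of a latent-skill player.

    Expected survival time (the score, in seconds) is maximal when the
    difficulty matches the player's skill and falls off as a Gaussian in the
    mismatch with width ``skill_width``.  Heart rate relaxes exponentially
    from the resting rate toward a plateau that increases with difficulty.
    Identical inputs (profile, difficulty, seed) give identical records.
    """
    if not d_min <= difficulty_in <= d_max:
        raise DomainError(f"difficulty_in {difficulty_in} outside [{d_min}, {d_max}]")
    rng = np.random.default_rng(rng_seed)
    mismatch = difficulty_in - profile.skill
    expected = session_length * math.exp(-(mismatch**2) / (2.0 * skill_width**2))
    score = max(0.0, expected + float(rng.normal(0.0, noise_sd)))

    plateau = profile.resting_hr + 30.0 + 50.0 * difficulty_in
    t = np.arange(session_length, dtype=float)
    hr = plateau - (plateau - profile.resting_hr) * np.exp(-t / 20.0)
    hr = hr + rng.normal(0.0, noise_sd / 4.0, size=session_length)
    hr = np.clip(hr, 30.0, None)

    return SessionRecord(
        session_index=session_index,
        score=score,
        hr_trace=tuple(float(v) for v in hr),
        difficulty_trace=tuple([difficulty_in] * session_length),
        end_difficulty=difficulty_in,
    )


def apply_action(cmd: "ActionCommand", state: GameState) -> GameState:
    """Apply a speed command to the game state, clamping to the bounds.

    Offline commands take effect at the next session boundary; real-time
    commands from the next tick.  Either way the result is the same state
    with the clamped new difficulty.
    """
    from .abstraction import ActionCommand  # avoid import cycle at module load

    if not isinstance(cmd, ActionCommand) or cmd.action_id != "speed":
        raise ActionError(f"unknown action {getattr(cmd, 'action_id', cmd)!r}")
    if cmd.target is not None:
        requested = cmd.target
    else:
        requested = state.difficulty + (cmd.delta or 0.0)
    new_difficulty = clip_difficulty(requested, state.d_min, state.d_max)
    return replace(state, difficulty=new_difficulty)
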