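"""Study runner: executes the personalization loop over a scenario.

One *study* replays a scenario through the full loop — game, feature
abstraction, interpreter, personalization engine, action abstraction — in
either offline mode (features evaluated after each session, difficulty
adapted for the next) or real-time mode (heart rate streamed at 1 Hz,
smoothed, and evaluated every few seconds during the session).  The
per-game summary compared across modes is the difficulty at the end of
each session, and the derived timing metrics say when each mode first
reduced the difficulty and when it reached its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .abstraction import (
    StudyHistory,
    locate_context,
    transform_action,
    transform_feature,
)
from .errors import DomainError, ScriptError
from .game import (
    D_MAX,
    D_MIN,
    D_START,
    SESSION_LENGTH,
    GameState,
    PlayerProfile,
    SessionRecord,
    apply_action,
    play_session_scripted,
)
from .knowledge import KnowledgeBase, default_knowledge_base
from .personalizer import (
    Interpreter,
    Mode,
    PersonalizationEngine,
    PersonalizedValue,
    ProcessedValue,
    RuleParams,
)
from .scenarios import Scenario

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Per-game difficulty trace of one study run plus derived metrics."""

    mode: Mode
    scenario: str
    difficulty_by_game: list[float]
    scores: list[float]
    mean_hr: list[float] | None
    commands: list[PersonalizedValue]
    sessions: list[SessionRecord] = field(default_factory=list)
    metrics: dict[str, float | int | None] = field(default_factory=dict)

    def trace_frame(self) -> pd.DataFrame:
        """Per-game trace as a data frame (game, mode, score, mean_hr,
        end_difficulty)."""
        n = len(self.difficulty_by_game)
        return pd.DataFrame(
            {
                "game": np.arange(1, n + 1),
                "mode": self.mode.value,
                "score": self.scores,
                "mean_hr": self.mean_hr if self.mean_hr is not None else [np.nan] * n,
                "end_difficulty": self.difficulty_by_game,
            }
        )

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = [
            f"Personalization study: scenario={self.scenario} mode={self.mode.value}",
            f"  games: {len(self.difficulty_by_game)}, commands: {len(self.commands)}",
        ]
        for key, value in self.metrics.items():
            lines.append(f"  {key}: {value}")
        return "\n".join(lines)


def compute_metrics(
    result: StudyResult, reference_min: float | None = None
) -> dict[str, float | int | None]:
    """Timing metrics of a difficulty trace (all game indices 1-based).

    * ``first_decrease_game`` — first game whose end-of-session difficulty
      is strictly below the previous game's (``None`` if none).
    * ``argmin_game`` — smallest game index attaining the trace minimum.
    * ``min_difficulty`` — the trace minimum.
    * ``reach_game`` — with a reference minimum (typically the other mode's
      minimum): first game at or below it (``None`` if never reached).
    """
    trace = result.difficulty_by_game
    if not trace:
        raise DomainError("empty difficulty trace")
    first_decrease = next(
        (g for g in range(2, len(trace) + 1) if trace[g - 1] < trace[g - 2]), None
    )
    min_difficulty = min(trace)
    argmin_game = trace.index(min_difficulty) + 1
    metrics: dict[str, float | int | None] = {
        "first_decrease_game": first_decrease,
        "argmin_game": argmin_game,
        "min_difficulty": min_difficulty,
    }
    if reference_min is not None:
        metrics["reach_game"] = next(
            (g for g in range(1, len(trace) + 1) if trace[g - 1] <= reference_min), None
        )
    return metrics


def _build_engine(model_id: str, params: RuleParams) -> PersonalizationEngine:
    engine = PersonalizationEngine(params=params)
    engine.activate(model_id)
    return engine


def _post_session_processed(
    record: SessionRecord,
    interpreter,
    kb: KnowledgeBase,
    history: StudyHistory,
    params: RuleParams,
) -> tuple[ProcessedValue, ProcessedValue | None]:
    """Interpret the end-of-session features: score and session-mean HR."""
    score_sample = transform_feature("score", record.score, record.session_index)
    score_ctx = locate_context("score", history, kb, window=params.trend_window)
    score_pv = interpreter.interpret(score_sample, kb.lookup("score"), score_ctx)

    hr_pv = None
    if record.hr_trace is not None:
        mean_hr = float(np.mean(record.hr_trace))
        hr_sample = transform_feature("heart_rate", mean_hr, record.session_index)
        hr_ctx = locate_context("heart_rate", history, kb)
        hr_pv = interpreter.interpret(hr_sample, kb.lookup("heart_rate"), hr_ctx)
    return score_pv, hr_pv


def run_offline_loop(
    scn: Scenario,
    model_id: str = "offline_score",
    profile: PlayerProfile | None = None,
    params: RuleParams | None = None,
    kb: KnowledgeBase | None = None,
    d_start: float = D_START,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
) -> StudyResult:
    """Run the loop in offline mode: adapt only at session boundaries.

    Game g plays at a difficulty fixed before it starts (game 1 at
    ``d_start``); after game g the features are interpreted and the model's
    command applies to game g+1.
    """
    params = params or RuleParams()
    profile = profile or PlayerProfile()
    kb = kb or default_knowledge_base(
        hr_override=scn.hr_max, window=params.trend_window, dead_band=params.dead_band
    )
    engine = _build_engine(model_id, params)
    if engine.active_registry[0].mode is not Mode.OFFLINE:
        raise DomainError(f"model {model_id!r} is not an offline model")
    interpreter = Interpreter(params)
    history = StudyHistory(age=profile.age, sex=profile.sex.value, intensity=profile.intensity)
    state = GameState(difficulty=d_start, d_min=d_min, d_max=d_max)
    result = StudyResult(
        mode=Mode.OFFLINE,
        scenario=scn.name,
        difficulty_by_game=[],
        scores=[],
        mean_hr=[] if scn.hr_scripts is not None else None,
        commands=[],
    )
    for g in range(1, scn.n_games + 1):
        hr_script = scn.hr_scripts[g - 1] if scn.hr_scripts is not None else None
        record = play_session_scripted(
            g,
            state.difficulty,
            scn.score_series[g - 1],
            hr_script,
            d_min=d_min,
            d_max=d_max,
        )
        result.sessions.append(record)
        result.scores.append(record.score)
        result.difficulty_by_game.append(record.end_difficulty)
        if result.mean_hr is not None:
            result.mean_hr.append(float(np.mean(record.hr_trace)))
        engine.start_session()
        score_pv, hr_pv = _post_session_processed(record, interpreter, kb, history, params)
        history.scores.append(record.score)
        pv = engine.evaluate_post_session(score_pv, hr_pv if "heart_rate" in
                                          engine.active_registry[0].inputs else None)
        if pv is not None:
            cmd = transform_action(pv)
            state = apply_action(cmd, state)
            logger.info(
                "game %d: %s -> delta %+.4f -> next difficulty %.3f",
                g, pv.origin_model, pv.delta, state.difficulty,
            )
    result.commands = list(engine.command_log)
    if result.difficulty_by_game:
        result.metrics = compute_metrics(result)
    return result


def run_realtime_loop(
    scn: Scenario,
    model_id: str = "realtime_score_hr",
    profile: PlayerProfile | None = None,
    params: RuleParams | None = None,
    kb: KnowledgeBase | None = None,
    d_start: float = D_START,
    d_min: float = D_MIN,
    d_max: float = D_MAX,
) -> StudyResult:
    """Run the loop in real-time mode.

    Within each session the heart rate is streamed at 1 Hz, EWMA-smoothed
    by the interpreter, and evaluated every ``t_eval`` seconds; immediate
    decrements apply from the next tick.  Difficulty carries over between
    sessions; the end-of-session score adjustment follows the real-time
    model's suppression rule.
    """
    params = params or RuleParams()
    profile = profile or PlayerProfile()
    if scn.hr_scripts is None:
        raise ScriptError("real-time mode needs per-tick heart-rate scripts")
    kb = kb or default_knowledge_base(
        hr_override=scn.hr_max, window=params.trend_window, dead_band=params.dead_band
    )
    engine = _build_engine(model_id, params)
    if engine.active_registry[0].mode is not Mode.REALTIME:
        raise DomainError(f"model {model_id!r} is not a real-time model")
    interpreter = Interpreter(params)
    history = StudyHistory(age=profile.age, sex=profile.sex.value, intensity=profile.intensity)
    hr_entry = kb.lookup("heart_rate")
    state = GameState(difficulty=d_start, d_min=d_min, d_max=d_max)
    result = StudyResult(
        mode=Mode.REALTIME,
        scenario=scn.name,
        difficulty_by_game=[],
        scores=[],
        mean_hr=[],
        commands=[],
    )
    for g in range(1, scn.n_games + 1):
        engine.start_session()
        hr_ctx = locate_context("heart_rate", history, kb)

        def hook(tick: int, raw_bpm: float, difficulty: float) -> float | None:
            nonlocal state
            sample = transform_feature("heart_rate", raw_bpm, g, tick=tick)
            pv_in = interpreter.interpret(sample, hr_entry, hr_ctx)
            pv = engine.evaluate_realtime(pv_in, scn.hr_max, tick)
            if pv is None:
                return None
            cmd = transform_action(pv)
            state = apply_action(cmd, state)
            logger.info(
                "game %d t=%ds: smoothed HR over ceiling -> delta %+.3f -> %.3f",
                g, tick, pv.delta, state.difficulty,
            )
            return state.difficulty

        record = play_session_scripted(
            g,
            state.difficulty,
            scn.score_series[g - 1],
            scn.hr_scripts[g - 1],
            realtime_hook=hook,
            d_min=d_min,
            d_max=d_max,
        )
        state = GameState(
            difficulty=record.end_difficulty, session_index=g, d_min=d_min, d_max=d_max
        )
        result.sessions.append(record)
        result.scores.append(record.score)
        result.mean_hr.append(float(np.mean(record.hr_trace)))
        result.difficulty_by_game.append(record.end_difficulty)
        score_pv, hr_pv = _post_session_processed(record, interpreter, kb, history, params)
        history.scores.append(record.score)
        pv = engine.evaluate_post_session(score_pv, hr_pv)
        if pv is not None:
            cmd = transform_action(pv)
            state = apply_action(cmd, state)
    result.commands = list(engine.command_log)
    if result.difficulty_by_game:
        result.metrics = compute_metrics(result)
    return result


def run_study(
    scn: Scenario,
    modes: tuple[str, ...] = ("offline", "realtime"),
    offline_model: str = "offline_score_hr",
    realtime_model: str = "realtime_score_hr",
    **kwargs,
) -> dict[str, StudyResult]:
    """Run a scenario in the requested modes and cross-derive reach metrics.

    When both modes run, the real-time result gains ``reach_game``: the
    first game whose end-of-session difficulty is at or below the offline
    run's global minimum.
    """
    results: dict[str, StudyResult] = {}
    if "offline" in modes:
        model = offline_model if scn.hr_scripts is not None else "offline_score"
        results["offline"] = run_offline_loop(scn, model_id=model, **kwargs)
    if "realtime" in modes:
        results["realtime"] = run_realtime_loop(scn, model_id=realtime_model, **kwargs)
    if "offline" in results and "realtime" in results:
        ref = results["offline"].metrics["min_difficulty"]
        results["realtime"].metrics = compute_metrics(
            results["realtime"], reference_min=float(ref)  # type: ignore[arg-type]
        )
    return results
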