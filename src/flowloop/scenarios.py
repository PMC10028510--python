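"""Deterministic simulation scenarios for the adaptation studies.

Four packaged 30-game scenarios exercise the personalization loop without
any external data.  The three score-only scenarios realize the qualitative
shapes of the simulated score series — diverging-then-constant, upward after
a dip, downward after a plateau — and the rising-heart-rate scenario is
constructed so three facts hold exactly: the instantaneous heart rate first
exceeds the 180 bpm ceiling during game 26, the session-mean heart rate
first exceeds it in game 27, and that mean is exactly 182 bpm.  Per-game
means rise by exactly 2 bpm/game (mean of game g is ``128 + 2g``), and
within each session the rate ramps linearly over +/-2 bpm around the mean.

All generators are seed-free and bit-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, ScriptError
from .game import SESSION_LENGTH

SCORE_SCENARIOS = ("fig7_constant", "fig8_upward", "fig9_downward")
HR_SCENARIOS = ("fig10_rising",)


@dataclass(frozen=True)
class Scenario:
    """Scripted inputs for one study: per-game scores, optional HR traces."""

    name: str
    n_games: int
    score_series: tuple[float, ...]
    hr_scripts: tuple[tuple[float, ...], ...] | None = None
    hr_max: float = 180.0

    def __post_init__(self) -> None:
        if len(self.score_series) != self.n_games:
            raise ScriptError(
                f"score series has {len(self.score_series)} entries for {self.n_games} games"
            )
        if self.hr_scripts is not None:
            if len(self.hr_scripts) != self.n_games:
                raise ScriptError("one HR script per game required")
            for g, script in enumerate(self.hr_scripts, start=1):
                if len(script) != SESSION_LENGTH:
                    raise ScriptError(
                        f"HR script of game {g} has {len(script)} samples, "
                        f"expected {SESSION_LENGTH}"
                    )


def gen_score_scenario(name: str) -> Scenario:
    """One of the three deterministic score-only scenarios.

    * ``fig7_constant`` — games 1-9 alternate 70/50, games 10-13 decline
      60, 52, 44, 38, game 14 jumps to 90, games 15-30 stay at 90.
    * ``fig8_upward`` — games 1-13 constant 60, games 14-15 dip 50, 48,
      games 16-30 rise by +7/game from 55.
    * ``fig9_downward`` — games 1-15 constant 60, games 16-26 fall by
      -5/game from 55, games 27-30 recover to a constant 40.
    """
    if name == "fig7_constant":
        series = (
            [70.0, 50.0] * 4 + [70.0]
            + [60.0, 52.0, 44.0, 38.0]
            + [90.0]
            + [90.0] * 16
        )
    elif name == "fig8_upward":
        series = [60.0] * 13 + [50.0, 48.0] + [55.0 + 7.0 * i for i in range(15)]
    elif name == "fig9_downward":
        series = [60.0] * 15 + [55.0 - 5.0 * i for i in range(11)] + [40.0] * 4
    else:
        raise DomainError(f"unknown score scenario {name!r}")
    return Scenario(name=name, n_games=30, score_series=tuple(series))


def gen_hr_scenario(name: str) -> Scenario:
    """The rising-heart-rate scenario with a constant score of 90.

    Game g's heart rate ramps linearly from ``m(g) - 2`` to ``m(g) + 2``
    over the 60 one-hertz samples, with ``m(g) = 128 + 2 g``; the session
    mean is therefore exactly ``m(g)``.  Ceiling 180 bpm.
    """
    if name != "fig10_rising":
        raise DomainError(f"unknown heart-rate scenario {name!r}")
    n_games = 30
    scripts = []
    for g in range(1, n_games + 1):
        m = 128.0 + 2.0 * g
        scripts.append(tuple(np.linspace(m - 2.0, m + 2.0, SESSION_LENGTH)))
    return Scenario(
        name=name,
        n_games=n_games,
        score_series=tuple([90.0] * n_games),
        hr_scripts=tuple(scripts),
        hr_max=180.0,
    )


def get_scenario(name: str) -> Scenario:
    if name in SCORE_SCENARIOS:
        return gen_score_scenario(name)
    if name in HR_SCENARIOS:
        return gen_hr_scenario(name)
    raise DomainError(f"unknown scenario {name!r}")


def export_scenario(scn: Scenario, out_dir: str | Path) -> list[Path]:
    """Write ``scores.csv`` (game, score) and, when present, ``hr.csv``
    (game, tick, bpm) under ``out_dir``; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    scores = pd.DataFrame(
        {"game": np.arange(1, scn.n_games + 1), "score": scn.score_series}
    )
    path = out / "scores.csv"
    scores.to_csv(path, index=False, float_format="%.17g")
    written.append(path)
    if scn.hr_scripts is not None:
        rows = [
            (g, t, bpm)
            for g, script in enumerate(scn.hr_scripts, start=1)
            for t, bpm in enumerate(script)
        ]
        hr = pd.DataFrame(rows, columns=["game", "tick", "bpm"])
        path = out / "hr.csv"
        hr.to_csv(path, index=False, float_format="%.17g")
        written.append(path)
    return written


def load_scenario(name: str, in_dir: str | Path, hr_max: float = 180.0) -> Scenario:
    """Reload a scenario previously written by :func:`export_scenario`."""
    in_dir = Path(in_dir)
    scores = pd.read_csv(in_dir / "scores.csv", float_precision="round_trip")
    score_series = tuple(float(v) for v in scores.sort_values("game")["score"])
    hr_scripts = None
    hr_path = in_dir / "hr.csv"
    if hr_path.exists():
        hr = pd.read_csv(hr_path, float_precision="round_trip")
        hr_scripts = tuple(
            tuple(float(v) for v in grp.sort_values("tick")["bpm"])
            for _, grp in hr.sort_values(["game", "tick"]).groupby("game", sort=True)
        )
    return Scenario(
        name=name,
        n_games=len(score_series),
        score_series=score_series,
        hr_scripts=hr_scripts,
        hr_max=hr_max,
    )
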