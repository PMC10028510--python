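"""Game-specific boundary between the game and the independent personalizer.

Three pieces keep the personalizer free of game knowledge:

* **Feature transformers** wrap game-native observations (a score, a heart
  rate sample) into generic :class:`FeatureSample` records — a lossless wrap,
  value and units pass through untouched.
* The **context locator** resolves, for a feature, exactly the context
  parameters its knowledge entry declares (player age/sex/intensity for the
  heart-rate ceiling, the previous N scores for the trend evaluator).
* The **action transformer** turns a generic personalized value back into a
  game command — here the single action is ``"speed"``, and the generic
  delta maps one-to-one onto a difficulty delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Mapping, Sequence

from .errors import ContextError, DomainError, TransformError
from .knowledge import KnowledgeBase

if TYPE_CHECKING:  # pragma: no cover
    from .personalizer import PersonalizedValue


class Phase(str, Enum):
    IN_SESSION = "in_session"
    POST_SESSION = "post_session"


class Timing(str, Enum):
    NEXT_SESSION = "next_session"
    IMMEDIATE = "immediate"


@dataclass(frozen=True)
class FeatureSample:
    """One game observation in the generic format the personalizer reads."""

    feature_id: str
    value: float  # bpm for heart_rate, score units for score
    session_index: int
    phase: Phase
    tick: int | None = None  # seconds within session; required in-session

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise DomainError(f"feature value must be finite, got {self.value}")
        if self.phase is Phase.IN_SESSION and self.tick is None:
            raise DomainError("in-session samples must carry a tick")


@dataclass(frozen=True)
class ContextBundle:
    """Values of exactly the context parameters a knowledge entry declares."""

    entries: Mapping[str, object]

    def __getitem__(self, key: str) -> object:
        return self.entries[key]

    def keys(self):
        return self.entries.keys()


@dataclass(frozen=True)
class ActionCommand:
    """Game-specific instruction leaving the loop.

    Exactly one of ``target`` (absolute difficulty) or ``delta`` (signed
    change) is set.  ``timing`` says whether it applies at the next session
    boundary or from the next tick.
    """

    action_id: str
    timing: Timing
    target: float | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        if (self.target is None) == (self.delta is None):
            raise DomainError("exactly one of target/delta must be set")


#: feature tags the shoulder-rehabilitation game exposes
GAME_FEATURES = ("score", "heart_rate")


def transform_feature(
    feature_id: str,
    value: float,
    session_index: int,
    tick: int | None = None,
    known_features: Sequence[str] = GAME_FEATURES,
) -> FeatureSample:
    """Wrap a tagged game-native observation into a :class:`FeatureSample`.

    The wrap is lossless: value and units pass through bit-exact.  Samples
    with a tick are in-session; samples without are post-session.
    """
    if feature_id not in known_features:
        raise TransformError(f"unknown feature tag {feature_id!r}")
    phase = Phase.IN_SESSION if tick is not None else Phase.POST_SESSION
    return FeatureSample(
        feature_id=feature_id,
        value=float(value),
        session_index=session_index,
        phase=phase,
        tick=tick,
    )


@dataclass
class StudyHistory:
    """What the context locator can draw on: player profile and past scores."""

    age: float
    sex: str
    intensity: float
    scores: list[float] = field(default_factory=list)


def locate_context(
    feature_id: str,
    history: StudyHistory,
    kb: KnowledgeBase,
    window: int | None = None,
) -> ContextBundle:
    """Resolve the context parameters declared for ``feature_id``.

    Returns exactly the declared parameters — no extras, no omissions.  For
    the score feature the previous scores are returned most recent last,
    truncated to the trend window when one is configured; sessions with
    fewer than ``window`` completed games use whatever is available.
    """
    entry = kb.lookup(feature_id)
    values: dict[str, object] = {}
    for name in entry.context_params:
        if name == "previous_scores":
            scores = list(history.scores)
            if window is not None:
                scores = scores[-window:]
            values[name] = tuple(scores)
        elif name in ("age", "sex", "intensity"):
            values[name] = getattr(history, name)
        else:
            raise ContextError(
                f"no history source for context parameter {name!r} of {feature_id!r}"
            )
    return ContextBundle(entries=values)


def transform_action(pv: "PersonalizedValue") -> ActionCommand:
    """Map a generic personalized value onto a game speed command.

    The generic delta is dimensionless and maps one-to-one onto a difficulty
    delta.  Commands from real-time models apply immediately (next tick);
    offline commands at the next session boundary.
    """
    if pv.action_id != "speed":
        raise TransformError(f"unknown action {pv.action_id!r}")
    return ActionCommand(action_id="speed", timing=pv.timing, delta=pv.delta)
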