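"""Knowledge base: formalized domain-expert knowledge for personalization.

The knowledge base holds, per feature, the knowledge *function* that gives a
raw observation meaning plus the names of the context parameters that function
needs.  For the shoulder-rehabilitation game two functions are registered: a
heart-rate ceiling (the highest heart rate accepted for a player of a given
age, sex and exercise intensity) and a score-trend evaluator (is the player's
performance flat, improving or declining over the last *N* games?).

The ceiling defaults to the classic age-predicted maximum, ``(220 - age)``
beats per minute, scaled by the prescribed exercise intensity; a fixed
override (e.g. a clinician-set 180 bpm) takes precedence when configured.

The trend evaluator fits an ordinary-least-squares line through the last
``window`` scores against game index 0..w-1 and normalizes the slope by the
window mean so the classification is invariant to the game's score scale.
A dead-band on the normalized slope absorbs noise: within it the trend is
*constant*, above it *upward*, below it *downward*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    DomainError,
    DuplicateFeatureError,
    InsufficientDataError,
    UnknownFeatureError,
)

#: guard against division by zero when normalizing the slope
EPS = 1e-9

#: default number of previous scores the trend evaluator looks at
DEFAULT_WINDOW = 5

#: default dead-band on the normalized slope (dimensionless)
DEFAULT_DEAD_BAND = 0.05


class KnowledgeKind(str, Enum):
    HR_CEILING = "hr_ceiling"
    SCORE_TREND = "score_trend"


class TrendClass(str, Enum):
    UPWARD = "upward"
    CONSTANT = "constant"
    DOWNWARD = "downward"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    OTHER = "other"


@dataclass(frozen=True)
class KnowledgeEntry:
    """One feature's knowledge function and its declared context parameters.

    Parameters
    ----------
    feature_id
        Unique identifier of the feature (``"heart_rate"``, ``"score"``).
    kind
        Which knowledge function interprets the feature.
    context_params
        Ordered names of the context parameters the function requires;
        must be non-empty.
    params
        Free-form knowledge parameters (e.g. ``override_hr_max``, ``window``,
        ``dead_band``).
    """

    feature_id: str
    kind: KnowledgeKind
    context_params: tuple[str, ...]
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.context_params:
            raise DomainError(f"entry {self.feature_id!r}: context_params must be non-empty")


@dataclass(frozen=True)
class TrendVerdict:
    """OLS slope of recent scores, its scale-free version, and the class."""

    slope: float  # score units per game
    norm_slope: float  # dimensionless: slope / window mean
    cls: TrendClass


@dataclass(frozen=True)
class HrCeiling:
    """Highest accepted heart rate, beats per minute."""

    hr_max: float

    def __post_init__(self) -> None:
        if not self.hr_max > 0:
            raise DomainError(f"hr_max must be positive, got {self.hr_max}")


class KnowledgeBase:
    """Registry of :class:`KnowledgeEntry` objects, one per feature."""

    def __init__(self) -> None:
        self._entries: dict[str, KnowledgeEntry] = {}

    def register_entry(self, entry: KnowledgeEntry) -> None:
        if entry.feature_id in self._entries:
            raise DuplicateFeatureError(
                f"feature {entry.feature_id!r} is already registered"
            )
        self._entries[entry.feature_id] = entry

    def lookup(self, feature_id: str) -> KnowledgeEntry:
        try:
            return self._entries[feature_id]
        except KeyError:
            raise UnknownFeatureError(f"no knowledge entry for feature {feature_id!r}") from None

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._entries

    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self._entries)


def eval_hr_max(
    age: float,
    sex: Sex | str,
    intensity: float,
    override: float | None = None,
) -> HrCeiling:
    """Highest accepted heart rate for the given context.

    Without an override the ceiling is the age-predicted maximum scaled by
    exercise intensity, ``(220 - age) * intensity``.  ``sex`` is part of the
    declared context (finer-grained formulas can use it) but does not enter
    the default formula.
    """
    if not age > 0:
        raise DomainError(f"age must be positive, got {age}")
    if not 0 < intensity <= 1:
        raise DomainError(f"intensity must lie in (0, 1], got {intensity}")
    Sex(sex)  # validates the enum value
    if override is not None:
        return HrCeiling(float(override))
    return HrCeiling((220.0 - age) * intensity)


def eval_score_trend(
    scores: Sequence[float],
    window: int = DEFAULT_WINDOW,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> TrendVerdict:
    """Classify the trend of the last ``min(window, len)`` scores.

    The slope is an OLS fit of score against game index ``0..w-1`` over the
    window; ``norm_slope = slope / max(|window mean|, EPS)``.  Classification
    uses only ``norm_slope``: above ``+dead_band`` is upward, below
    ``-dead_band`` downward, otherwise constant.
    """
    if len(scores) < 2:
        raise InsufficientDataError(
            f"need at least 2 scores for a trend, got {len(scores)}"
        )
    if window < 2:
        raise DomainError(f"window must be >= 2, got {window}")
    y = np.asarray(scores, dtype=float)[-window:]
    x = np.arange(len(y), dtype=float)
    # closed-form OLS slope; exactly zero for a flat series
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    norm_slope = slope / max(abs(float(y.mean())), EPS)
    if norm_slope > dead_band:
        cls = TrendClass.UPWARD
    elif norm_slope < -dead_band:
        cls = TrendClass.DOWNWARD
    else:
        cls = TrendClass.CONSTANT
    return TrendVerdict(slope=slope, norm_slope=norm_slope, cls=cls)


def default_knowledge_base(
    hr_override: float | None = 180.0,
    window: int = DEFAULT_WINDOW,
    dead_band: float = DEFAULT_DEAD_BAND,
) -> KnowledgeBase:
    """Knowledge base of the shoulder-rehabilitation proof of concept.

    Two entries: the heart-rate ceiling (context: age, sex, intensity) and
    the score-trend evaluator (context: previous scores).
    """
    kb = KnowledgeBase()
    hr_params: dict[str, float] = {}
    if hr_override is not None:
        hr_params["override_hr_max"] = float(hr_override)
    kb.register_entry(
        KnowledgeEntry(
            feature_id="heart_rate",
            kind=KnowledgeKind.HR_CEILING,
            context_params=("age", "sex", "intensity"),
            params=hr_params,
        )
    )
    kb.register_entry(
        KnowledgeEntry(
            feature_id="score",
            kind=KnowledgeKind.SCORE_TREND,
            context_params=("previous_scores",),
            params={"window": window, "dead_band": dead_band},
        )
    )
    return kb
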