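"""Game- and domain-independent personalization core.

The **Interpreter** combines a generic feature sample with the knowledge
entry for that feature and the located context, producing a
:class:`ProcessedValue`: a signed "personalization need" on [-1, 1].  The
sign convention, used everywhere in the package, is *positive = reduce
challenge/load, negative = increase challenge*.

The **Personalization Engine** routes processed values to pluggable models
via its model locator and collects the :class:`PersonalizedValue` commands
they emit.  Three rule-based models are built in:

* ``offline_score`` — trend-following difficulty steps after each session:
  a slow fixed increase while the score trend is constant, proportional
  (gain ``slope_gain``, clipped at ``max_step``) steps while it is upward
  or downward.
* ``offline_score_hr`` — heart-rate safety wrapped around the score model,
  with strict precedence: a session-mean heart rate over the ceiling forces
  a fixed decrement; a still-rising sub-ceiling heart rate holds the
  difficulty; only otherwise does the score model act.
* ``realtime_score_hr`` — during the session, smoothed heart rate is
  checked at every evaluation instant and each exceedance of the ceiling
  triggers an immediate small decrement; at session end the score model
  runs only if no immediate command was issued and the heart rate is not
  rising.

In-session heart-rate samples are smoothed with an exponentially weighted
moving average (EWMA) seeded with the first sample of each session.  None
of the step magnitudes are physiological constants; they are tunable rule
parameters (see :class:`RuleParams`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .abstraction import ContextBundle, FeatureSample, Phase, Timing
from .errors import (
    ContextError,
    DomainError,
    ModelConfigurationError,
    RoutingError,
)
from .knowledge import (
    KnowledgeEntry,
    KnowledgeKind,
    TrendClass,
    TrendVerdict,
    eval_hr_max,
    eval_score_trend,
)


class Mode(str, Enum):
    OFFLINE = "offline"
    REALTIME = "realtime"


@dataclass(frozen=True)
class RuleParams:
    """Tunable constants of the built-in rule models.

    All values are dimensionless difficulty steps unless noted.
    """

    constant_step: float = 0.01  # per-game increase while the trend is flat
    slope_gain: float = 0.5  # difficulty step per unit normalized slope
    max_step: float = 0.08  # clip on trend-proportional offline steps
    hr_over_step: float = 0.05  # offline decrement when session mean > ceiling
    realtime_step: float = 0.02  # immediate decrement per exceedance
    t_eval: int = 5  # seconds between real-time evaluation instants
    ewma_alpha: float = 0.3  # EWMA smoothing weight for streamed heart rate
    rising_threshold: float = 1.0  # bpm/session increase that counts as rising
    trend_window: int = 5  # previous scores the trend evaluator sees
    dead_band: float = 0.05  # normalized-slope dead-band for "constant"

    def __post_init__(self) -> None:
        if not 0 < self.ewma_alpha <= 1:
            raise DomainError(f"ewma_alpha must lie in (0, 1], got {self.ewma_alpha}")
        if self.t_eval < 1:
            raise DomainError(f"t_eval must be >= 1, got {self.t_eval}")


@dataclass(frozen=True)
class ProcessedValue:
    """Game-agnostic personalization need produced by the interpreter."""

    feature_id: str
    need: float  # in [-1, 1]; positive = reduce challenge
    session_index: int
    phase: Phase
    over_limit: bool = False
    rising: bool = False  # heart rate only
    trend: TrendVerdict | None = None  # score only

    def __post_init__(self) -> None:
        if abs(self.need) > 1:
            raise DomainError(f"|need| must be <= 1, got {self.need}")
        if self.over_limit and not self.need > 0:
            raise DomainError("over_limit implies a positive need")


@dataclass(frozen=True)
class PersonalizedValue:
    """Generic adaptation command emitted by a model."""

    action_id: str
    delta: float
    origin_model: str
    timing: Timing


@dataclass(frozen=True)
class ModelSpec:
    """Declaration of a personalization model: its inputs and mode."""

    model_id: str
    inputs: frozenset[str]
    mode: Mode

    def __post_init__(self) -> None:
        if self.mode is Mode.REALTIME and "heart_rate" not in self.inputs:
            raise DomainError(
                "real-time models must take heart_rate (the only in-session stream)"
            )


#: specs of the three built-in rule models
BUILTIN_MODELS = {
    "offline_score": ModelSpec("offline_score", frozenset({"score"}), Mode.OFFLINE),
    "offline_score_hr": ModelSpec(
        "offline_score_hr", frozenset({"score", "heart_rate"}), Mode.OFFLINE
    ),
    "realtime_score_hr": ModelSpec(
        "realtime_score_hr", frozenset({"score", "heart_rate"}), Mode.REALTIME
    ),
}


def _clip(x: float, lo: float, hi: float) -> float:
    return min(max(x, lo), hi)


class Interpreter:
    """Gives meaning to feature samples using knowledge and context.

    Stateful across a study: it remembers the previous session-mean heart
    rate (to set the *rising* flag) and keeps the per-session EWMA of
    streamed heart-rate samples.
    """

    def __init__(self, params: RuleParams | None = None) -> None:
        self.params = params or RuleParams()
        self._prev_session_mean: float | None = None
        self._ewma: float | None = None
        self._ewma_session: int | None = None

    def reset(self) -> None:
        self._prev_session_mean = None
        self._ewma = None
        self._ewma_session = None

    def smoothed_hr(self) -> float | None:
        """Current in-session EWMA of the heart rate, if any."""
        return self._ewma

    def interpret(
        self, sample: FeatureSample, entry: KnowledgeEntry, ctx: ContextBundle
    ) -> ProcessedValue:
        if set(ctx.keys()) != set(entry.context_params):
            raise ContextError(
                f"context {sorted(ctx.keys())} does not match declared "
                f"parameters {sorted(entry.context_params)} for {entry.feature_id!r}"
            )
        if entry.kind is KnowledgeKind.HR_CEILING:
            return self._interpret_heart_rate(sample, entry, ctx)
        if entry.kind is KnowledgeKind.SCORE_TREND:
            return self._interpret_score(sample, entry, ctx)
        raise ContextError(f"no interpretation for knowledge kind {entry.kind}")

    # -- heart rate -------------------------------------------------------

    def _interpret_heart_rate(
        self, sample: FeatureSample, entry: KnowledgeEntry, ctx: ContextBundle
    ) -> ProcessedValue:
        ceiling = eval_hr_max(
            age=float(ctx["age"]),
            sex=str(ctx["sex"]),
            intensity=float(ctx["intensity"]),
            override=entry.params.get("override_hr_max"),
        )
        hr_max = ceiling.hr_max
        if sample.phase is Phase.IN_SESSION:
            value = self._update_ewma(sample)
            rising = False
        else:
            value = sample.value  # session-mean heart rate
            rising = (
                self._prev_session_mean is not None
                and value - self._prev_session_mean > self.params.rising_threshold
            )
            self._prev_session_mean = value
        need = _clip((value - hr_max) / hr_max, -1.0, 1.0)
        return ProcessedValue(
            feature_id=sample.feature_id,
            need=need,
            session_index=sample.session_index,
            phase=sample.phase,
            over_limit=value > hr_max,
            rising=rising,
        )

    def _update_ewma(self, sample: FeatureSample) -> float:
        alpha = self.params.ewma_alpha
        if self._ewma is None or self._ewma_session != sample.session_index:
            self._ewma = sample.value  # EWMA seeded with the first sample
            self._ewma_session = sample.session_index
        else:
            self._ewma = alpha * sample.value + (1 - alpha) * self._ewma
        return self._ewma

    # -- score ------------------------------------------------------------

    def _interpret_score(
        self, sample: FeatureSample, entry: KnowledgeEntry, ctx: ContextBundle
    ) -> ProcessedValue:
        previous = list(ctx["previous_scores"])  # type: ignore[arg-type]
        series = previous + [sample.value]
        window = int(entry.params.get("window", self.params.trend_window))
        dead_band = float(entry.params.get("dead_band", self.params.dead_band))
        if len(series) < 2:
            # first session: no trend yet, no adaptation need
            return ProcessedValue(
                feature_id=sample.feature_id,
                need=0.0,
                session_index=sample.session_index,
                phase=sample.phase,
            )
        trend = eval_score_trend(series, window=window, dead_band=dead_band)
        need = -_clip(trend.norm_slope, -1.0, 1.0)
        return ProcessedValue(
            feature_id=sample.feature_id,
            need=need,
            session_index=sample.session_index,
            phase=sample.phase,
            trend=trend,
        )


def route_model(pv: ProcessedValue, registry: Sequence[ModelSpec]) -> str:
    """Model locator: pick the active model that accepts this processed value.

    A model matches when its inputs contain the feature and its mode matches
    the phase (in-session values go to real-time models, post-session values
    to offline models).  Exactly one active model may match.
    """
    if not registry:
        raise RoutingError("empty model registry")
    wanted = Mode.REALTIME if pv.phase is Phase.IN_SESSION else Mode.OFFLINE
    matches = [m for m in registry if pv.feature_id in m.inputs and m.mode is wanted]
    if not matches:
        raise RoutingError(
            f"no {wanted.value} model registered for feature {pv.feature_id!r}"
        )
    if len(matches) > 1:
        raise ModelConfigurationError(
            f"ambiguous routing for {pv.feature_id!r}: "
            + ", ".join(m.model_id for m in matches)
        )
    return matches[0].model_id


# -- built-in rule models --------------------------------------------------


def model_offline_score(
    trend: TrendVerdict, params: RuleParams | None = None, origin: str = "offline_score"
) -> PersonalizedValue:
    """Trend-following offline difficulty step."""
    p = params or RuleParams()
    if trend.cls is TrendClass.CONSTANT:
        delta = p.constant_step
    else:
        delta = _clip(p.slope_gain * trend.norm_slope, -p.max_step, p.max_step)
    return PersonalizedValue(
        action_id="speed", delta=delta, origin_model=origin, timing=Timing.NEXT_SESSION
    )


def model_offline_score_hr(
    trend: TrendVerdict | None,
    hr: ProcessedValue,
    params: RuleParams | None = None,
) -> PersonalizedValue | None:
    """Offline model with heart-rate precedence over the score trend.

    Precedence: ceiling exceeded > heart rate rising > score trend.  With no
    trend available yet (first session) and no heart-rate condition active,
    no command is emitted.
    """
    p = params or RuleParams()
    if hr.over_limit:
        return PersonalizedValue(
            action_id="speed",
            delta=-p.hr_over_step,
            origin_model="offline_score_hr",
            timing=Timing.NEXT_SESSION,
        )
    if hr.rising:
        return PersonalizedValue(
            action_id="speed",
            delta=0.0,
            origin_model="offline_score_hr",
            timing=Timing.NEXT_SESSION,
        )
    if trend is None:
        return None
    return model_offline_score(trend, p, origin="offline_score_hr")


def model_realtime_score_hr(
    smoothed_hr: float, hr_max: float, params: RuleParams | None = None
) -> PersonalizedValue | None:
    """Immediate decrement while the smoothed heart rate exceeds the ceiling."""
    p = params or RuleParams()
    if smoothed_hr > hr_max:
        return PersonalizedValue(
            action_id="speed",
            delta=-p.realtime_step,
            origin_model="realtime_score_hr",
            timing=Timing.IMMEDIATE,
        )
    return None


class PersonalizationEngine:
    """Routes processed values to the active models and collects commands.

    Several models may be registered simultaneously; the engine activates
    exactly one per mode for a study run.  Per session it tracks whether any
    immediate command was issued, which suppresses the end-of-session score
    adjustment of the real-time model.
    """

    def __init__(
        self,
        registry: Sequence[ModelSpec] | None = None,
        active: Sequence[str] | None = None,
        params: RuleParams | None = None,
    ) -> None:
        self.params = params or RuleParams()
        specs = list(registry) if registry is not None else list(BUILTIN_MODELS.values())
        self._specs = {m.model_id: m for m in specs}
        self._active: list[str] = list(active) if active is not None else []
        self._issued_immediate: bool = False
        self.command_log: list[PersonalizedValue] = []

    def activate(self, *model_ids: str) -> None:
        for mid in model_ids:
            if mid not in self._specs:
                raise RoutingError(f"unknown model {mid!r}")
        self._active = list(model_ids)

    @property
    def active_registry(self) -> list[ModelSpec]:
        return [self._specs[mid] for mid in self._active]

    def start_session(self) -> None:
        self._issued_immediate = False

    def evaluate_realtime(
        self, hr_pv: ProcessedValue, hr_max: float, tick: int
    ) -> PersonalizedValue | None:
        """Evaluate the streamed (smoothed) heart rate at evaluation instants.

        Called once per tick; acts only every ``t_eval`` seconds of session
        time.  ``hr_pv.need`` encodes the smoothed exceedance, so the model
        is invoked with the smoothed value reconstructed from it.
        """
        if (tick + 1) % self.params.t_eval != 0:
            return None
        model_id = route_model(hr_pv, self.active_registry)
        if model_id != "realtime_score_hr":
            raise RoutingError(f"model {model_id!r} cannot run in-session")
        # need encodes the smoothed relative exceedance: smoothed = hr_max*(1+need)
        smoothed = hr_max * (1.0 + hr_pv.need)
        pv = model_realtime_score_hr(smoothed, hr_max, self.params)
        if pv is not None:
            self._issued_immediate = True
            self.command_log.append(pv)
        return pv

    def evaluate_post_session(
        self,
        score_pv: ProcessedValue | None,
        hr_pv: ProcessedValue | None,
    ) -> PersonalizedValue | None:
        """Run the active offline-routed model after a completed session."""
        anchor = score_pv or hr_pv
        if anchor is None:
            return None
        # post-session values go to the active offline model when one exists;
        # an active real-time model handles its own session-end rule
        candidates = [m for m in self.active_registry if anchor.feature_id in m.inputs]
        offline = [m for m in candidates if m.mode is Mode.OFFLINE]
        pool = offline or candidates
        if not pool:
            raise RoutingError(
                f"no active model accepts feature {anchor.feature_id!r}"
            )
        if len(pool) > 1:
            raise ModelConfigurationError(
                "ambiguous post-session routing: " + ", ".join(m.model_id for m in pool)
            )
        model_id = pool[0].model_id
        trend = score_pv.trend if score_pv is not None else None
        if model_id == "offline_score":
            pv = model_offline_score(trend, self.params) if trend is not None else None
        elif model_id == "offline_score_hr":
            if hr_pv is None:
                raise RoutingError("offline_score_hr needs a heart-rate processed value")
            pv = model_offline_score_hr(trend, hr_pv, self.params)
        elif model_id == "realtime_score_hr":
            # end-of-session rule: score adjustment only if the session saw no
            # immediate command and the heart rate is not rising
            if self._issued_immediate or (hr_pv is not None and hr_pv.rising):
                pv = None
            else:
                pv = model_offline_score(trend, self.params) if trend is not None else None
        else:
            raise RoutingError(f"no implementation for model {model_id!r}")
        if pv is not None:
            self.command_log.append(pv)
        return pv
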