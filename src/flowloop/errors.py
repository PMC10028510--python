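"""Exception hierarchy for the personalization loop."""


class FlowloopError(Exception):
    """Base class for all package errors."""


class DuplicateFeatureError(FlowloopError):
    """A feature id was registered twice in a knowledge base."""


class UnknownFeatureError(FlowloopError, KeyError):
    """Lookup of a feature id that was never registered."""


class DomainError(FlowloopError, ValueError):
    """A physiological or game parameter outside its valid range."""


class InsufficientDataError(FlowloopError):
    """Not enough observations to evaluate a knowledge function."""


class ScriptError(FlowloopError):
    """A scripted session input does not match the session geometry."""


class ActionError(FlowloopError):
    """An action command references an unknown game action."""


class ContextError(FlowloopError):
    """Required context parameters cannot be resolved from history."""


class TransformError(FlowloopError):
    """A raw observation carries an unknown feature tag."""


class RoutingError(FlowloopError):
    """No registered model accepts a processed value."""


class ModelConfigurationError(FlowloopError):
    """More than one active model matches the same processed value."""


class ConfigError(FlowloopError):
    """A run configuration file failed validation."""
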