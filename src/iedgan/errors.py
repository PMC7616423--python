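"""Exception hierarchy for the package."""


class IedganError(Exception):
    """Base class for package errors."""


class InvalidParameterError(IedganError, ValueError):
    """A configuration or call parameter is out of its valid range."""


class InvalidInputError(IedganError, ValueError):
    """Input data violates a precondition (empty, single-class, ...)."""


class ShapeError(IedganError, ValueError):
    """Array input has the wrong shape."""


class MissingChannelError(IedganError, KeyError):
    """A requested channel label is absent from a recording."""


class SimulationError(IedganError, RuntimeError):
    """The requested synthetic recording is infeasible (e.g. too many events)."""


class ConfigurationError(IedganError, ValueError):
    """A model architecture configuration is inconsistent."""


class EmptySelectionError(IedganError, ValueError):
    """No training subjects met the selection threshold."""
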