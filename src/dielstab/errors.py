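"""Exception hierarchy shared by all pipeline stages."""


class DielstabError(Exception):
    """Base class for all package errors."""


class ValidationError(DielstabError, ValueError):
    """Input violates a declared invariant (bad bounds, non-monotone grid, ...)."""


class FormatError(DielstabError, ValueError):
    """A file does not match the declared tabular dialect (e.g. missing column)."""


class EmptyInputError(DielstabError, ValueError):
    """A file or collection contained no usable rows."""


class DomainError(DielstabError, ValueError):
    """A function was evaluated outside its mathematical domain."""


class InitializationError(DielstabError, RuntimeError):
    """No automatic starting point could be derived and none was supplied."""


class UnderdeterminedError(DielstabError, ValueError):
    """Too few data points to constrain the requested fit."""


class EmptyResultError(DielstabError, RuntimeError):
    """A stage that must produce at least one result produced none."""


class OutOfRangeError(DielstabError, ValueError):
    """A value falls outside the invertible range of a model.

    Carries ``distance``: how far (in the input's units) the value lies
    beyond the nearest admissible endpoint.
    """

    def __init__(self, message: str, distance: float = float("nan")):
        super().__init__(message)
        self.distance = distance
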