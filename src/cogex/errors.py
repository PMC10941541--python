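"""Exception types shared across the package."""


class CogexError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CogexError, ValueError):
    """A parameter is outside its allowed range."""


class MissingRegionError(CogexError, ValueError):
    """A region required by an operation is covered by no donor."""

    def __init__(self, regions):
        self.regions = list(regions)
        super().__init__(f"regions covered by no donor: {self.regions}")


class DegenerateInputError(CogexError, ValueError):
    """Input has no usable variance (constant map, zero-variance column, ...)."""


class CollinearityError(CogexError, ValueError):
    """Design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class ConvergenceError(CogexError, RuntimeError):
    """An iterative fit failed to converge; carries the optimizer trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class InsufficientOverlapError(CogexError, ValueError):
    """Too few matched items (e.g. genes) to compare two models."""


class UndefinedCongruenceError(CogexError, ValueError):
    """Congruence requested against an all-zero loading vector."""


class AmbiguousAssignmentError(CogexError, ValueError):
    """Duplicate centroids make the spin assignment ill-defined."""


class IncompleteInputError(CogexError, ValueError):
    """A multi-part input (e.g. one table per measure) is missing a part."""


class NotIdentifiableError(CogexError, ValueError):
    """A model has more free parameters than the data can identify."""
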