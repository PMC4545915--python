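"""Exception types shared across the package."""


class PurecellError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PurecellError, ValueError):
    """A cohort or pipeline configuration violates its invariants."""


class InvalidInputError(PurecellError, ValueError):
    """Input values violate an operation's preconditions."""


class DegenerateSampleError(InvalidInputError):
    """A sample column carries no usable signal (e.g. all-zero abundances)."""


class ScaleError(InvalidInputError):
    """An expression matrix is on the wrong scale for the requested operation."""


class ScaleMismatchWarning(UserWarning):
    """A column's scale deviates from its declared convention but was accepted."""


class DegenerateSignatureError(InvalidInputError):
    """A gene signature is empty after intersection or spans the whole universe."""


class InsufficientSamplesError(InvalidInputError):
    """Too few samples for the requested statistic."""


class StageError(PurecellError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
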