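"""Exception types shared across the pipeline."""


class EpiturnError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EpiturnError, ValueError):
    """A value violates a type invariant or precondition."""


class DomainError(EpiturnError, ValueError):
    """A numeric argument is outside its physical domain."""


class InsufficientDataError(EpiturnError, ValueError):
    """Too few observations to perform the requested computation."""


class DegeneratePrecursorError(EpiturnError, ValueError):
    """Precursor enrichment is zero/undefined, so fractional synthesis is not computable."""
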