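"""Exception hierarchy for the phenology pipeline.

Retrieval-stage failures are ordinary events (an always-source year has no
spring transition); they are caught at the ``retrieve_*`` boundaries and
encoded in result objects rather than propagated to callers.
"""


class FluxPhenoError(Exception):
    """Base class for all package errors."""


class FormatError(FluxPhenoError):
    """A file does not match the expected columnar layout."""


class ValidationError(FluxPhenoError):
    """A series violates a structural invariant (ordering, lengths, ranges)."""


class InsufficientDataError(FluxPhenoError):
    """Too few valid observations to run an operation."""


class EmptySeriesError(InsufficientDataError):
    """Every value in a series is missing."""


class NoCrossingError(FluxPhenoError):
    """A noise-free NEE curve never changes sign."""


class NoTransitionError(FluxPhenoError):
    """No window with the required source/sink sign pattern exists."""

    def __init__(self, direction: str, message: str | None = None):
        self.direction = direction
        super().__init__(message or f"no {direction} transition window found")


class WrongSlopeError(FluxPhenoError):
    """The transition-window regression slope has the wrong sign."""


class DegenerateFitError(FluxPhenoError):
    """A regression is degenerate (zero slope, no variance)."""


class DegenerateAmplitudeError(FluxPhenoError):
    """Seasonal amplitude below the floor; no retrievable phenology."""


class FitFailureError(FluxPhenoError):
    """Nonlinear curve fit failed from every starting point."""


class ParameterError(FluxPhenoError):
    """Generator or configuration parameters are invalid."""


class GenerationError(FluxPhenoError):
    """A synthetic site-year could not be constructed as designed."""


class OutOfRangeError(FluxPhenoError):
    """An accumulation window extends outside the calendar year."""


class MissingDataError(FluxPhenoError):
    """Required daily values inside an accumulation window are missing."""


class NoCandidateError(FluxPhenoError):
    """No candidate impact window had enough complete site-years."""


class CollinearityError(FluxPhenoError):
    """Rank-deficient regression design."""


class FoldError(FluxPhenoError):
    """A leave-one-out fold could not be fitted."""


class PairingError(FluxPhenoError):
    """Paired date vectors have mismatched lengths."""
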