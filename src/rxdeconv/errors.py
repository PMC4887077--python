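"""Exception hierarchy for rxdeconv.

All package errors derive from :class:`RxDeconvError` so callers can catch
one base class at pipeline boundaries.
"""


class RxDeconvError(Exception):
    """Base class for all rxdeconv errors."""


class InvalidInputError(RxDeconvError, ValueError):
    """An input violates a documented precondition (negative entry, bad shape, ...)."""


class DegenerateSampleError(InvalidInputError):
    """A sample column is entirely zero and cannot be normalized."""


class AlignmentError(InvalidInputError):
    """Gene identifiers of two containers do not match in content and order."""


class InvalidWeightsError(InvalidInputError):
    """A mixture-weight vector is off the probability simplex beyond tolerance."""


class BoundaryError(InvalidInputError):
    """A simplex point lies on the boundary where a Dirichlet density is undefined."""


class NonFiniteLikelihoodError(RxDeconvError):
    """A likelihood term evaluated to NaN/inf; the message names the term."""


class FitFailureError(RxDeconvError):
    """Every random restart produced a non-finite objective."""


class UndefinedCorrelationError(RxDeconvError):
    """Correlation requested against a constant vector."""


class InsufficientOverlapError(RxDeconvError):
    """Too few shared genes between the delta profile and a reference panel."""


class ParseError(RxDeconvError, ValueError):
    """A text input file is malformed; the message cites the line number."""


class ConfigError(RxDeconvError, ValueError):
    """A run configuration is inconsistent or references missing inputs."""
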