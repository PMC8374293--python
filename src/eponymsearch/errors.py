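"""Exception taxonomy for the eponym search pipeline.

All package exceptions derive from :class:`EponymSearchError` so callers can
catch pipeline failures without catching programming errors.
"""


class EponymSearchError(Exception):
    """Base class for all errors raised by this package."""


class InputError(EponymSearchError):
    """A required input file is missing or unreadable."""


class SchemaError(EponymSearchError):
    """An input file lacks a required column or has an unusable layout."""


class ValidationError(EponymSearchError):
    """A value violates a documented invariant (empty term, duplicate phrase, ...)."""


class AmbiguityError(ValidationError):
    """An operation cannot decide between several readings and needs manual input.

    Raised e.g. for a prepositional eponym with more than one "of", or for
    planted corpus phrases where one phrase is a substring of another.
    """


class UnsupportedArityError(EponymSearchError):
    """The permutation grammar has no pattern set for this many surnames."""


class MedlineParseError(EponymSearchError):
    """A MEDLINE text block could not be parsed into a citation record."""


class TransportFailure(EponymSearchError):
    """A transport-level failure (network, HTTP, service outage).

    Transports raise this for failures that are worth retrying.  A
    well-formed response carrying warnings is *not* a transport failure.
    """


class TransientFailureError(EponymSearchError):
    """A transport failure that persisted through all retry attempts.

    Carries the pagination offset reached so a caller can resume.
    """

    def __init__(self, message: str, retstart: int | None = None):
        super().__init__(message)
        self.retstart = retstart


class IntegrityError(EponymSearchError):
    """The service returned inconsistent data across pages of one query."""
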