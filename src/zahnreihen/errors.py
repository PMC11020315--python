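"""Exception hierarchy shared across the package."""


class ZahnreihenError(Exception):
    """Base class for all package errors."""


class FormatError(ZahnreihenError):
    """An input file is structurally malformed (e.g. a required column is absent)."""


class ValidationError(ZahnreihenError):
    """A record violates a domain invariant (negative length, duplicate tooth, ...)."""


class UndefinedSpacingError(ZahnreihenError):
    """Z-spacing requested for a dentition with fewer than two Zahnreihen."""


class NotInferableError(ZahnreihenError):
    """The replacement-rate rule does not apply to the supplied tooth."""


class OrderingError(ZahnreihenError):
    """Specimens cannot be placed in ontogenetic order, or family counts are mis-ordered."""


class DegenerateDataError(ZahnreihenError):
    """A model fit was requested on data that cannot identify any rate (monomorphic tips)."""


class AllocationError(ZahnreihenError):
    """A stochastic-map budget cannot be split across the weighted models."""
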