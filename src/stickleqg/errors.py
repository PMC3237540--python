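"""Shared exception types."""


class StickleQGError(Exception):
    """Base class for package errors."""


class InputError(StickleQGError, ValueError):
    """Invalid or inconsistent user input."""


class DegenerateDataError(StickleQGError, ValueError):
    """Data carry no information for the requested fit (e.g. constant response)."""


class ReferenceError_(StickleQGError, KeyError):
    """An id referenced by the data is missing from the pedigree/panel."""


class ComparabilityError(StickleQGError, ValueError):
    """Two model fits cannot be compared (different data or non-nested)."""


class PrecisionError(StickleQGError, ValueError):
    """Too few draws/loci/observations for the requested summary."""


class EstimationError(StickleQGError, ValueError):
    """No information left to estimate from (e.g. no polymorphic locus)."""
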