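"""Exception hierarchy shared across the pipeline.

Every stage raises one of these rather than a bare ``ValueError`` so that the
CLI and pipeline runner can report which contract was violated.
"""


class PhenocapError(Exception):
    """Base class for all package errors."""


class ParameterError(PhenocapError):
    """A parameter violates a stated invariant (the message names it)."""


class StructuralError(PhenocapError):
    """Input table/series malformed: unsorted, misaligned, or mismatched."""


class CoverageError(PhenocapError):
    """A timestamp or date range falls outside the data actually covered."""


class DataQualityError(PhenocapError):
    """Data present but unusable (e.g. unfilled missing hours)."""


class DegenerateDataError(PhenocapError):
    """Data formally valid but uninformative (e.g. all-zero counts)."""


class InsufficientDataError(PhenocapError):
    """Too few groups/years for the requested resampling scheme."""
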