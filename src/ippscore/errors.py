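"""Exception hierarchy.

Every distinct failure mode named by the public API raises its own class so
callers can discriminate without string matching.
"""


class IPPError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdentifierError(IPPError):
    """Gene or sample identifiers are not unique."""


class NonNumericValueError(IPPError):
    """Expression body contains a value that is not a finite number."""


class EmptyCohortError(IPPError):
    """No sample survives the expression/clinical join or validity filters."""


class EmptyGeneSetError(IPPError):
    """A gene filter removed every gene."""


class InvalidCNACallError(IPPError):
    """A copy-number call outside the five recognised levels."""


class EmptyGroupError(IPPError):
    """A survival group passed to a two-group test is empty."""


class MissingDirectionError(IPPError):
    """One-sided p-value requested without an alternative direction."""


class UnknownGeneError(IPPError):
    """Requested gene is absent from the cohort's expression matrix."""


class GeneUniverseMismatchError(IPPError):
    """Per-dataset score tables do not share one gene universe."""
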