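"""Exception hierarchy for helifil.

Contracts in the public API raise these rather than bare built-ins, so callers
can distinguish a malformed input file from a geometric degeneracy.  Where the
semantics match a built-in (bad argument values, missing keys) the class also
inherits from it.
"""


class HelifilError(Exception):
    """Base class for all helifil-specific errors."""


class ParseError(HelifilError):
    """A structure file could not be parsed; names the offending line/field."""


class ValidationError(HelifilError, ValueError):
    """An argument or domain object violates a documented precondition."""


class FormatCapacityError(HelifilError, ValueError):
    """The requested output format cannot represent the structure."""


class DegeneracyError(HelifilError, ValueError):
    """A geometric operation is undefined for this input (collinear points,
    identity screw, spherical subunit...)."""


class StitchingError(HelifilError, ValueError):
    """Loop endpoints are incompatible with the junction they should close."""


class NoContactError(HelifilError, ValueError):
    """No inter-subunit contacts exist at any offset/cutoff."""


class UndefinedMetricError(HelifilError, ValueError):
    """An interface metric is undefined (e.g. empty buried patch)."""


class InsufficientDataError(HelifilError, ValueError):
    """Too few data points for the requested estimate."""
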