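"""Exception hierarchy for the glycocall pipeline.

Every error raised by the library derives from :class:`GlycocallError` so
callers (and the CLI) can catch pipeline failures without masking bugs.
"""


class GlycocallError(Exception):
    """Base class for all glycocall errors."""


class FormatError(GlycocallError):
    """A file does not conform to the expected GPR/ATF layout."""


class ParseError(GlycocallError):
    """A cell inside an otherwise well-formed file could not be parsed."""


class IntegrityError(GlycocallError):
    """Data violates a structural invariant (duplicate keys, bad fixture)."""


class ConditionError(GlycocallError):
    """Scan conditions are missing, swapped, or duplicated."""


class JoinError(GlycocallError):
    """A join between tables referenced an unknown identifier."""


class EmptyInputError(GlycocallError):
    """An operation that needs at least one record received none."""


class UndefinedRatioError(GlycocallError):
    """A ratio with zero denominator was requested at spot level."""


class ParameterError(GlycocallError):
    """Simulation or sweep parameters violate their invariants."""
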