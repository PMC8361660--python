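"""Exception hierarchy shared across the package."""


class OsteocladError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OsteocladError):
    """Malformed or invariant-violating input file.

    Readers raise this instead of silently repairing bad rows; the message
    names the offending line or segment where possible.
    """


class InfeasibleConfigError(OsteocladError):
    """A simulation or planting request that cannot be satisfied."""


class ClockViolationError(OsteocladError):
    """Clock-mutation counts do not increase with collection time."""


class ConvergenceError(OsteocladError):
    """An iterative fit failed to reach its tolerance."""
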