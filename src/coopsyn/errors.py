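"""Typed exceptions shared across the package."""


class CoopsynError(Exception):
    """Base class for all coopsyn errors."""


class ValidationError(CoopsynError, ValueError):
    """An input violates a documented precondition or invariant."""


class UndefinedCombinationEffectError(CoopsynError):
    """The combination effect is zero, so a combination index is undefined.

    A zero denominator means the combination produced no measurable
    inhibition; reporting an infinite CI would be misleading, so callers
    must handle this case explicitly.
    """


class InsufficientDataError(CoopsynError):
    """Too few usable measurements for the requested computation."""


class NotReachedError(CoopsynError):
    """No tested dose attains the required inhibition level (e.g. 50%)."""
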