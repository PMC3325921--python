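"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates one of its structural invariants."""


class UndefinedParameterError(ValueError):
    """A per-gene parameter is undefined for the given call pattern.

    Raised instead of returning a sentinel so that "no up-calls" is never
    silently conflated with a score of zero.
    """
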