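"""Exception types shared across the package."""


class TweedieDomainError(ValueError):
    """Parameter or argument outside the supported Tweedie domain."""


class SeriesConvergenceError(ArithmeticError):
    """The Dunn-Smyth series did not reach the requested tolerance."""


class PanelValidationError(ValueError):
    """An observation panel violates its structural invariants."""


class DivergentStateError(ArithmeticError):
    """A parameter state produced non-finite or overflowing means."""
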